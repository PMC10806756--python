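"""Annotation, region and multiple-testing filters over raw SMR results.

Candidate associations must map to an annotated protein-coding gene outside
the MHC, pass a Bonferroni-corrected multi-SNP SMR threshold, and show no
evidence of linkage heterogeneity (p_HEIDI above a floor).  Exclusions are
evaluated in a fixed order (annotation -> coding -> MHC -> p_SMR_multi ->
p_HEIDI) so per-rule counts are reproducible; a row is counted against the
first rule it fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MHC_HG19",
    "SignificanceConfig",
    "bonferroni_threshold",
    "annotate_mhc",
    "apply_filters",
    "relaxed_pleiotropy_lookup",
    "EXCLUSION_ORDER",
]

#: extended MHC interval, hg19, 1-based inclusive (configurable at call sites)
MHC_HG19 = ("6", 28_477_797, 33_448_354)

#: rounded thresholds as printed in the source study; metadata only — all
#: filtering uses exact quotients from :func:`bonferroni_threshold`
PRINTED_DISEASE_LEVEL_THRESHOLD = 2.95e-6
PRINTED_ALL_OMICS_THRESHOLD = 1.58e-8

EXCLUSION_ORDER = [
    "no_annotation",
    "not_protein_coding",
    "in_mhc",
    "p_smr_multi",
    "heidi_missing",
    "p_heidi",
]


def bonferroni_threshold(alpha: float, n: int) -> float:
    """Family-wise threshold alpha/n (exact quotient, never a rounded print)."""
    if n < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / n


@dataclass(frozen=True)
class SignificanceConfig:
    """Family error rate and test-count bookkeeping for candidate selection.

    Defaults correspond to alpha = 0.05 over 16,875 protein-coding genes with
    HEIDI consistency required at p > 0.01, and a relaxed exploratory lookup
    threshold of 0.05.
    """

    alpha: float = 0.05
    n_genes_tested: int = 16_875
    p_heidi_min: float = 0.01
    relaxed_p: float = 0.05

    def __post_init__(self):
        for name in ("alpha", "p_heidi_min", "relaxed_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1)")
        if self.n_genes_tested < 1:
            raise ValueError("n_genes_tested must be positive")

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.n_genes_tested)


def annotate_mhc(annot: pd.DataFrame, mhc=MHC_HG19) -> pd.DataFrame:
    """Add/refresh the ``in_mhc`` flag from span overlap with ``mhc``."""
    chrom, lo, hi = mhc
    out = annot.copy()
    out["in_mhc"] = (
        (out["chrom"].astype(str) == str(chrom))
        & (out["start"] <= hi)
        & (out["end"] >= lo)
    )
    return out


def apply_filters(
    results: pd.DataFrame,
    annot: pd.DataFrame,
    cfg: SignificanceConfig = SignificanceConfig(),
    mhc=MHC_HG19,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain candidate associations; report per-rule exclusion counts.

    ``results`` needs columns ``gene``, ``p_SMR_multi``, ``p_HEIDI``;
    ``annot`` needs ``gene``, ``chrom``, ``start``, ``end``,
    ``protein_coding``.  Returns ``(retained, exclusions)`` where exclusion
    counts (first matching rule wins) plus the retained count partition the
    input rows.  A missing p_HEIDI does not pass the HEIDI rule but is
    tallied separately under ``heidi_missing``.
    """
    ann = annotate_mhc(annot, mhc).set_index("gene")
    known = results["gene"].isin(ann.index)
    coding = pd.Series(False, index=results.index)
    mhc_hit = pd.Series(False, index=results.index)
    if known.any():
        coding.loc[known] = (
            ann["protein_coding"].reindex(results.loc[known, "gene"]).to_numpy()
        )
        mhc_hit.loc[known] = (
            ann["in_mhc"].reindex(results.loc[known, "gene"]).to_numpy()
        )

    thr = cfg.threshold
    sig = results["p_SMR_multi"] < thr
    heidi_na = results["p_HEIDI"].isna()
    heidi_ok = results["p_HEIDI"] > cfg.p_heidi_min

    reason = pd.Series("retained", index=results.index)
    reason[~heidi_ok & ~heidi_na] = "p_heidi"
    reason[heidi_na] = "heidi_missing"
    reason[~sig] = "p_smr_multi"
    reason[mhc_hit] = "in_mhc"
    reason[known & ~coding] = "not_protein_coding"
    reason[~known] = "no_annotation"

    exclusions = {k: int((reason == k).sum()) for k in EXCLUSION_ORDER}
    exclusions["retained"] = int((reason == "retained").sum())
    retained = results[reason == "retained"].reset_index(drop=True)
    return retained, exclusions


def relaxed_pleiotropy_lookup(
    candidate_genes,
    results: pd.DataFrame,
    relaxed_p: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Sub-threshold lookup restricted to an established candidate gene set.

    Used to probe pleiotropic sharing with a disease that yielded no
    genome-wide candidates of its own: rows of ``results`` whose gene is in
    ``candidate_genes`` and whose p_SMR_multi falls below ``relaxed_p`` are
    returned together with the unique-gene count.
    """
    candidate_genes = set(candidate_genes)
    if not candidate_genes:
        raise ValueError("candidate gene set is empty")
    hits = results[
        results["gene"].isin(candidate_genes)
        & (results["p_SMR_multi"] < relaxed_p)
    ].reset_index(drop=True)
    return hits, int(hits["gene"].nunique())
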