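"""Multi-disease overlap, direction consensus, replication, and tier triage.

The druggability tier scheme partitions nominated genes into:

* ``novel``     — druggable, but no therapeutic approved for any of the study's
                  neurodegenerative diseases targets the gene;
* ``known``     — druggable and already targeted by an NDD-approved drug;
* ``difficult`` — not annotated as druggable by any snapshot source.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "NDD_DISEASES",
    "disease_overlap",
    "direction_consensus",
    "replicate_multi_ancestry",
    "classify_tiers",
]

NDD_DISEASES = frozenset({"AD", "ALS", "FTLD", "LBD", "PD", "PSP"})


def disease_overlap(assocs: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per gene the set of diseases and association count.

    ``assocs`` needs ``gene`` and ``disease`` columns (post-filter output).
    Rows are ordered by descending disease count, then gene symbol, so the
    output is invariant to input row permutation.
    """
    if assocs.empty:
        return pd.DataFrame(columns=["gene", "diseases", "n_diseases", "n_assoc"])
    grp = assocs.groupby("gene")
    out = pd.DataFrame(
        {
            "gene": grp.size().index,
            "diseases": grp["disease"].agg(lambda s: tuple(sorted(set(s)))).to_numpy(),
            "n_diseases": grp["disease"].nunique().to_numpy(),
            "n_assoc": grp.size().to_numpy(),
        }
    )
    return (
        out.sort_values(["n_diseases", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def direction_consensus(assocs: pd.DataFrame) -> pd.DataFrame:
    """Fraction of positive SMR betas per gene with a consensus label.

    A gene is "positive" when more than half of its significant associations
    carry a positive beta_SMR, "negative" below half, and "split" at exactly
    one half.  Zero betas violate the results invariant and raise.
    """
    if (assocs["b_SMR"] == 0).any():
        raise ValueError("zero beta_SMR encountered")
    grp = assocs.groupby("gene")["b_SMR"]
    frac = grp.apply(lambda s: float((s > 0).mean()))
    label = frac.map(
        lambda f: "positive" if f > 0.5 else ("negative" if f < 0.5 else "split")
    )
    return pd.DataFrame(
        {"gene": frac.index, "frac_positive": frac.to_numpy(), "consensus": label.to_numpy()}
    ).reset_index(drop=True)


def replicate_multi_ancestry(
    candidates: pd.DataFrame,
    ma_results: pd.DataFrame,
    cfg,
) -> tuple[list[str], pd.DataFrame]:
    """Replication of candidate genes in multi-ancestry results.

    ``candidates`` are filtered reference-panel associations (``gene``,
    ``b_SMR``); ``ma_results`` are associations from the multi-ancestry run
    (``gene``, ``b_SMR``, ``p_SMR_multi``, ``p_HEIDI``).  A gene replicates
    when any multi-ancestry association passes ``cfg``'s thresholds.  The
    concordance table labels each candidate gene "concordant"/"discordant" by
    majority sign agreement of betas between the two panels, or "untested"
    when absent from the multi-ancestry results.
    """
    thr = cfg.threshold
    passing = ma_results[
        (ma_results["p_SMR_multi"] < thr) & (ma_results["p_HEIDI"] > cfg.p_heidi_min)
    ]
    cand_genes = sorted(candidates["gene"].unique())
    eur_sign = candidates.groupby("gene")["b_SMR"].apply(
        lambda s: 1 if (s > 0).mean() >= 0.5 else -1
    )
    ma_sign = passing.groupby("gene")["b_SMR"].apply(
        lambda s: 1 if (s > 0).mean() >= 0.5 else -1
    )
    rows = []
    replicated = []
    for g in cand_genes:
        if g not in ma_sign.index:
            rows.append({"gene": g, "replicated": False, "concordance": "untested"})
            continue
        replicated.append(g)
        agree = eur_sign[g] == ma_sign[g]
        rows.append(
            {
                "gene": g,
                "replicated": True,
                "concordance": "concordant" if agree else "discordant",
            }
        )
    return replicated, pd.DataFrame(rows, columns=["gene", "replicated", "concordance"])


def _ndd_approved_drugs(gene, indications, ndd_diseases):
    hit = indications[
        (indications["gene"] == gene)
        & indications["disease"].isin(ndd_diseases)
        & (indications["approval_status"] == "approved")
    ]
    return sorted(hit["drug"].unique())


def classify_tiers(
    genes,
    druggable,
    indications: pd.DataFrame,
    ndd_diseases=NDD_DISEASES,
    aliases: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assign each gene to exactly one druggability tier.

    ``druggable`` is the snapshot gene set from druggable-genome /
    drug-gene-interaction sources; ``indications`` has columns ``drug``,
    ``gene``, ``disease``, ``approval_status``.  Only *approved* indications
    for one of ``ndd_diseases`` promote a gene to ``known``; trials-only
    evidence does not.  ``aliases`` maps input symbols to snapshot symbols
    first; genes absent from the druggability snapshot are "difficult" and
    flagged ``unannotated``.
    """
    aliases = aliases or {}
    druggable = set(druggable)
    annotated = druggable | set(indications["gene"])
    rows = []
    for g in sorted(set(genes)):
        sym = aliases.get(g, g)
        is_druggable = sym in druggable
        drugs = _ndd_approved_drugs(sym, indications, ndd_diseases)
        if not is_druggable:
            tier = "difficult"
        elif drugs:
            tier = "known"
        else:
            tier = "novel"
        rows.append(
            {
                "gene": g,
                "tier": tier,
                "druggable": is_druggable,
                "ndd_approved_drugs": drugs,
                "unannotated": sym not in annotated,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "tier", "druggable", "ndd_approved_drugs", "unannotated"]
    )
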