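"""Companion-gene network triage over curated directed interaction edges.

A companion of a seed gene is a direct curated regulator (upstream) or target
(downstream) in the interaction snapshot — one hop only, no transitive
closure.  Companions can then be annotated with druggability/proxy-drug
evidence and flagged when they (or the seeds) show filtered liver-tissue SMR
signal, a proxy for hepatic drug-toxicity concerns.
"""

from __future__ import annotations

import pandas as pd

from .tiers import NDD_DISEASES, _ndd_approved_drugs

__all__ = [
    "expand_companions",
    "annotate_proxy_drugs",
    "liver_toxicity_flags",
]

REPORT_COLUMNS = ["seed_gene", "companion", "direction", "relation", "source"]


def expand_companions(seed: str, edges: pd.DataFrame, depth: int = 1) -> pd.DataFrame:
    """Direct curated partners of ``seed`` (one hop by default).

    ``edges`` has columns ``regulator``, ``target``, ``relation``, ``source``.
    Regulators of the seed are reported as ``upstream``, targets as
    ``downstream``; output is sorted (direction, companion) so it is invariant
    to edge-row permutation.  A seed absent from the table yields an empty
    frame with ``attrs["note"] == "no network"``.
    """
    if depth != 1:
        raise NotImplementedError("only one-hop neighborhoods are supported")
    present = (edges["regulator"] == seed).any() or (edges["target"] == seed).any()
    up = edges[edges["target"] == seed]
    down = edges[edges["regulator"] == seed]
    rows = [
        pd.DataFrame(
            {
                "seed_gene": seed,
                "companion": up["regulator"],
                "direction": "upstream",
                "relation": up["relation"],
                "source": up["source"],
            }
        ),
        pd.DataFrame(
            {
                "seed_gene": seed,
                "companion": down["target"],
                "direction": "downstream",
                "relation": down["relation"],
                "source": down["source"],
            }
        ),
    ]
    out = (
        pd.concat(rows, ignore_index=True)
        .drop_duplicates(subset=["companion", "direction"])
        .sort_values(["direction", "companion"], kind="mergesort")
        .reset_index(drop=True)
    )
    out = out[out["companion"] != seed]
    if not present:
        out.attrs["note"] = "no network"
    return out


def annotate_proxy_drugs(
    reports: pd.DataFrame,
    druggable,
    indications: pd.DataFrame,
    ndd_diseases=NDD_DISEASES,
) -> pd.DataFrame:
    """Fill druggability and proxy-drug evidence for each companion.

    Adds ``druggable``, ``known_drugs`` (any drug targeting the companion) and
    ``ndd_approved`` (an approved indication for a study disease exists),
    using the same snapshot rules as tier classification.  The companion set
    itself is never changed.
    """
    druggable = set(druggable)
    out = reports.copy()
    if out.empty:
        out["druggable"] = pd.Series(dtype=bool)
        out["known_drugs"] = pd.Series(dtype=object)
        out["ndd_approved"] = pd.Series(dtype=bool)
        return out
    out["druggable"] = out["companion"].map(lambda g: g in druggable)
    out["known_drugs"] = out["companion"].map(
        lambda g: sorted(indications.loc[indications["gene"] == g, "drug"].unique())
    )
    out["ndd_approved"] = out["companion"].map(
        lambda g: bool(_ndd_approved_drugs(g, indications, ndd_diseases))
    )
    return out


def liver_toxicity_flags(
    reports: pd.DataFrame,
    seeds,
    liver_results: pd.DataFrame,
) -> pd.DataFrame:
    """Flag seeds and companions with filtered liver-tissue SMR signal.

    ``liver_results`` are post-filter candidate associations restricted to
    liver tissue (``gene``, ``disease``).  Returns one row per seed or
    companion gene with ``liver_flag`` and the disease contexts in which the
    liver signal appears.  Adding liver associations can only turn flags on.
    """
    ctx = (
        liver_results.groupby("gene")["disease"].agg(lambda s: sorted(set(s)))
        if len(liver_results)
        else pd.Series(dtype=object)
    )
    genes = sorted(set(seeds) | set(reports["companion"]) if len(reports) else set(seeds))
    rows = []
    for g in genes:
        diseases = ctx.get(g, [])
        rows.append(
            {
                "gene": g,
                "is_seed": g in set(seeds),
                "liver_flag": bool(diseases),
                "contexts": diseases,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "is_seed", "liver_flag", "contexts"])
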