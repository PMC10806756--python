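"""Final target-nomination report joining all pipeline stages."""

from __future__ import annotations

import json

import pandas as pd

from .tiers import direction_consensus, disease_overlap

__all__ = ["build_report", "write_report"]

REPORT_COLUMNS = [
    "gene", "diseases", "n_assoc", "consensus", "tier",
    "n_companions", "n_druggable_companions", "n_proxy_ndd_drugs",
    "liver_flag", "epr_support", "replication",
]


def _check_schema(frame: pd.DataFrame, cols, stage: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"stage {stage!r}: missing column(s) {missing}")


def build_report(
    candidates: pd.DataFrame,
    tiers: pd.DataFrame,
    companions: pd.DataFrame | None = None,
    liver_flags: pd.DataFrame | None = None,
    epr_categories: pd.Series | None = None,
    ma_concordance: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the per-gene nomination report and its tally sidecar.

    ``candidates`` are filtered associations (``gene``, ``disease``,
    ``b_SMR``); ``tiers`` is the tier table; the remaining stages are
    optional and reported as "untested"/absent when not supplied.  Returns
    ``(report, tallies)`` where tallies hold per-disease association counts
    and per-tier gene counts; every reported gene lands in exactly one tier
    tally and the association tally equals the candidate row count.
    """
    _check_schema(candidates, ["gene", "disease", "b_SMR"], "candidates")
    _check_schema(tiers, ["gene", "tier"], "tiers")

    overlap = disease_overlap(candidates).set_index("gene")
    consensus = direction_consensus(candidates).set_index("gene")
    tier_map = tiers.set_index("gene")["tier"]

    comp_counts = None
    if companions is not None and len(companions):
        _check_schema(companions, ["seed_gene", "companion"], "companions")
        grp = companions.groupby("seed_gene")
        comp_counts = pd.DataFrame(
            {
                "n_companions": grp["companion"].nunique(),
                "n_druggable_companions": grp["druggable"].sum()
                if "druggable" in companions
                else 0,
                "n_proxy_ndd_drugs": grp["ndd_approved"].sum()
                if "ndd_approved" in companions
                else 0,
            }
        )
    liver_map = (
        liver_flags.set_index("gene")["liver_flag"]
        if liver_flags is not None and len(liver_flags)
        else pd.Series(dtype=bool)
    )
    repl_map = (
        ma_concordance.set_index("gene")["concordance"]
        if ma_concordance is not None and len(ma_concordance)
        else pd.Series(dtype=object)
    )

    rows = []
    for gene in overlap.index:
        tier = tier_map.get(gene, "difficult")
        row = {
            "gene": gene,
            "diseases": ",".join(overlap.loc[gene, "diseases"]),
            "n_assoc": int(overlap.loc[gene, "n_assoc"]),
            "consensus": consensus.loc[gene, "consensus"],
            "tier": tier,
            "n_companions": 0,
            "n_druggable_companions": 0,
            "n_proxy_ndd_drugs": 0,
            "liver_flag": bool(liver_map.get(gene, False)),
            "epr_support": (
                epr_categories.get(gene, "untested")
                if epr_categories is not None
                else "untested"
            ),
            "replication": repl_map.get(gene, "untested"),
        }
        if comp_counts is not None and gene in comp_counts.index:
            row["n_companions"] = int(comp_counts.loc[gene, "n_companions"])
            row["n_druggable_companions"] = int(
                comp_counts.loc[gene, "n_druggable_companions"]
            )
            row["n_proxy_ndd_drugs"] = int(comp_counts.loc[gene, "n_proxy_ndd_drugs"])
        rows.append(row)
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)

    tallies = {
        "n_associations": int(len(candidates)),
        "n_genes": int(report["gene"].nunique()),
        "per_disease": candidates.groupby("disease").size().to_dict(),
        "per_tier": report.groupby("tier").size().to_dict(),
    }
    return report, tallies


def write_report(report: pd.DataFrame, tallies: dict, tsv_path, json_path) -> None:
    report.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")
    with open(json_path, "w") as fh:
        json.dump(tallies, fh, indent=2, sort_keys=True)
        fh.write("\n")
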