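"""Expression percentile ranks (EPR) from single-nucleus counts.

Per cell, feature counts are length-normalized to TPM (divide by exon length,
rescale so the cell sums to one million).  A gene's EPR in a cell is its
percentile under the empirical cumulative distribution of that cell's TPM
values (ties share the maximal rank of their tie group), averaged per gene
across the cells of each cell type, and binned for interpretation:

    off  : mean EPR < 10
    low  : 10 <= mean EPR <= 90
    high : mean EPR > 90

(the boundary values 10 and 90 are assigned to ``low``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "counts_to_tpm",
    "epr_ranks",
    "epr_bin",
    "aggregate_epr",
    "expression_summary",
    "exon_lengths_from_gtf",
    "read_counts_mtx",
    "write_counts_mtx",
    "DEFAULT_RELEVANT_CELL_TYPES",
]

#: disease-relevant adult human brain cell types (overridable at call sites)
DEFAULT_RELEVANT_CELL_TYPES = (
    "Bergmann glia",
    "CGE interneuron",
    "Committed oligodendrocyte precursor",
    "Deep-layer intratelencephalic",
    "Eccentric medium spiny neuron",
    "Hippocampal CA1-3",
    "Hippocampal dentate gyrus",
    "LAMP5",
    "LHX6 and Chandelier",
    "MGE interneuron",
    "Mammillary body",
    "Microglia",
    "Midbrain-derived inhibitory",
    "Oligodendrocyte precursor",
    "Thalamic excitatory",
    "Upper-layer intratelencephalic",
    "Upper rhombic lip",
)

OFF_BELOW = 10.0
HIGH_ABOVE = 90.0


def counts_to_tpm(counts: pd.DataFrame, exon_length: pd.Series) -> pd.DataFrame:
    """Length-normalize a genes x cells counts matrix to TPM.

    ``exon_length`` gives each gene's maximum nonredundant intron-removed
    exon length in base pairs.  Every output column sums to 1e6.  An all-zero
    cell cannot be normalized and raises, naming the cell.
    """
    lengths = exon_length.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"genes without exon length: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("exon lengths must be positive")
    rate = counts.div(lengths, axis=0)
    total = rate.sum(axis=0)
    dead = total[total == 0]
    if len(dead):
        raise ValueError(f"all-zero cell(s): {dead.index.tolist()[:5]}")
    return rate.div(total, axis=1) * 1e6


def epr_ranks(tpm: pd.DataFrame) -> pd.DataFrame:
    """Within-cell percentile ranks of TPM via the ECDF, in (0, 100].

    A gene's EPR is 100 * (# genes with TPM <= its TPM) / (# genes); tied
    genes share the maximal rank of their tie group.  Invariant to any
    per-cell monotone rescaling of TPM.
    """
    ranks = rankdata(tpm.to_numpy(), method="max", axis=0)
    return pd.DataFrame(
        100.0 * ranks / tpm.shape[0], index=tpm.index, columns=tpm.columns
    )


def epr_bin(mean_epr: float) -> str:
    if mean_epr < OFF_BELOW:
        return "off"
    if mean_epr > HIGH_ABOVE:
        return "high"
    return "low"


def aggregate_epr(epr: pd.DataFrame, cell_type: pd.Series) -> pd.DataFrame:
    """Mean/median EPR per gene x cell type, binned off/low/high on the mean.

    ``cell_type`` maps cell id -> type label for every column of ``epr``.
    Cell types with no cells are simply absent from the output.
    """
    missing = [c for c in epr.columns if c not in cell_type.index]
    if missing:
        raise ValueError(f"cells without a cell type: {missing[:5]}")
    types = cell_type.reindex(epr.columns)
    rows = []
    for ct, cols in epr.T.groupby(types):
        vals = cols.T  # genes x cells of this type
        mean = vals.mean(axis=1)
        med = vals.median(axis=1)
        for g in epr.index:
            rows.append(
                {
                    "gene": g,
                    "cell_type": ct,
                    "mean_epr": float(mean[g]),
                    "median_epr": float(med[g]),
                    "bin": epr_bin(float(mean[g])),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "cell_type", "mean_epr", "median_epr", "bin"])


def expression_summary(
    records: pd.DataFrame,
    relevant_types=None,
) -> dict:
    """Per-gene expression-support categories and per-cell-type tallies.

    Against the observed cell-type universe, each gene is categorized
    ``all_off`` (off everywhere), ``all_low`` (low everywhere), ``any_high``
    (high somewhere) or ``mixed`` (otherwise: some off, some low, never high);
    the four categories partition the gene set.  When ``relevant_types`` is
    given the same categorization is recomputed restricted to those types
    (``restricted`` key).  Genes missing some cell types are counted against
    the types they were observed in and listed under ``incomplete_genes``.
    """
    universe = sorted(records["cell_type"].unique())

    def categorize(sub: pd.DataFrame) -> pd.Series:
        def one(bins: pd.Series) -> str:
            if (bins == "high").any():
                return "any_high"
            if (bins == "off").all():
                return "all_off"
            if (bins == "low").all():
                return "all_low"
            return "mixed"

        return sub.groupby("gene")["bin"].apply(one)

    cats = categorize(records)
    counts = records.groupby("gene")["cell_type"].nunique()
    incomplete = sorted(counts.index[counts < len(universe)])

    per_type = (
        records.groupby(["cell_type", "bin"]).size().unstack(fill_value=0)
        .reindex(columns=["off", "low", "high"], fill_value=0)
    )

    out = {
        "universe": universe,
        "categories": cats,
        "category_counts": cats.value_counts().to_dict(),
        "per_cell_type": per_type,
        "incomplete_genes": incomplete,
    }
    if relevant_types is not None:
        sub = records[records["cell_type"].isin(set(relevant_types))]
        rcats = categorize(sub) if len(sub) else pd.Series(dtype=object)
        out["restricted"] = {
            "categories": rcats,
            "category_counts": rcats.value_counts().to_dict(),
        }
    return out


def exon_lengths_from_gtf(path) -> pd.Series:
    """Union of exon intervals per gene from a GTF, summed (strand-ignored).

    Expects ``gene_id "..."`` attributes on exon features; returns base pairs
    per gene id.
    """
    import re

    spans: dict[str, list[tuple[int, int]]] = {}
    pat = re.compile(r'gene_id "([^"]+)"')
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "exon":
                continue
            m = pat.search(parts[8])
            if not m:
                continue
            spans.setdefault(m.group(1), []).append((int(parts[3]), int(parts[4])))
    lengths = {}
    for gene, ivals in spans.items():
        ivals.sort()
        total = 0
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
        lengths[gene] = total
    return pd.Series(lengths, name="exon_length")


def write_counts_mtx(counts: pd.DataFrame, cell_type: pd.Series,
                     exon_length: pd.Series, prefix) -> None:
    """Write counts as MatrixMarket plus genes.tsv / cells.tsv sidecars."""
    from scipy import io as spio
    from scipy import sparse

    spio.mmwrite(f"{prefix}.mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.DataFrame(
        {"gene": counts.index, "exon_length": exon_length.reindex(counts.index)}
    ).to_csv(f"{prefix}.genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"cell": counts.columns, "cell_type": cell_type.reindex(counts.columns)}
    ).to_csv(f"{prefix}.cells.tsv", sep="\t", index=False)


def read_counts_mtx(prefix) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Read the MTX + sidecar layout written by :func:`write_counts_mtx`."""
    from scipy import io as spio

    mat = spio.mmread(f"{prefix}.mtx").toarray()
    genes = pd.read_csv(f"{prefix}.genes.tsv", sep="\t")
    cells = pd.read_csv(f"{prefix}.cells.tsv", sep="\t")
    counts = pd.DataFrame(mat, index=genes["gene"], columns=cells["cell"])
    return (
        counts,
        cells.set_index("cell")["cell_type"],
        genes.set_index("gene")["exon_length"],
    )
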