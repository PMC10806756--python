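"""Reading, validation, harmonization and serialization of summary statistics.

GWAS associations travel in the whitespace-separated "ma" layout
(``SNP A1 A2 freq b se p n``); cis-QTL data travel either as a long-format TSV
or as the three-file store written by :func:`serialize_qtl` (a variant index, a
probe index and a per-probe effects table — a plain-text analogue of the
binary three-file QTL stores used by reference SMR tooling).  All coordinates
are 1-based hg19; genome-build conversion is a pre-step outside this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStatRecord",
    "QTLProbe",
    "LDPanel",
    "SumstatsFormatError",
    "read_gwas_ma",
    "write_gwas_ma",
    "read_qtl_long",
    "harmonize",
    "z_to_beta_se",
    "serialize_qtl",
    "load_qtl",
    "write_ld_panel",
    "read_ld_panel",
]

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "n"]

#: canonical internal column names for one variant's association evidence
REC_COLUMNS = ["snp", "a1", "a2", "freq", "b", "se", "p", "n"]

QTL_LONG_COLUMNS = [
    "probe", "gene", "omic", "tissue", "ancestry",
    "snp", "chrom", "pos", "a1", "a2", "freq", "b", "se", "p",
]

OMIC_KINDS = frozenset({"eQTL", "mQTL", "pQTL", "caQTL"})

#: reserved missing-value sentinel in all text stores (never silently zero)
NA_SENTINEL = "NA"


class SumstatsFormatError(ValueError):
    """A summary-statistics file violates its documented layout."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association evidence (effect allele = ``a1``)."""

    snp_id: str
    a1: str
    a2: str
    freq_a1: float
    beta: float
    se: float
    p: float
    n: float
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self):
        if self.a1 == self.a2:
            raise ValueError(f"{self.snp_id}: identical alleles {self.a1}")
        if not (0.0 <= self.freq_a1 <= 1.0):
            raise ValueError(f"{self.snp_id}: freq {self.freq_a1} outside [0,1]")
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.snp_id}: p {self.p} outside (0,1]")


@dataclass
class QTLProbe:
    """A molecular trait (gene / CpG / protein / peak) with cis summary stats.

    ``records`` is a DataFrame with :data:`REC_COLUMNS` plus ``chrom``/``pos``
    per variant, all on the probe's chromosome.
    """

    probe_id: str
    chrom: str
    probe_pos: int
    omic: str
    tissue: str
    records: pd.DataFrame
    gene_symbol: str | None = None
    ancestry: str = "EUR"

    def __post_init__(self):
        if self.omic not in OMIC_KINDS:
            raise ValueError(f"unknown omic kind {self.omic!r}")
        if len(self.records) and "chrom" in self.records:
            off = self.records["chrom"].astype(str) != str(self.chrom)
            if off.any():
                bad = self.records.loc[off, "snp"].tolist()
                raise ValueError(
                    f"probe {self.probe_id}: records off-chromosome: {bad[:5]}"
                )

    @property
    def omic_tissue(self) -> str:
        return f"{self.tissue} {self.omic}"


@dataclass
class LDPanel:
    """Hard-call reference genotypes used to estimate LD correlations.

    ``genotypes`` holds allele dosages (0/1/2) of ``effect_allele`` for
    ``n_samples`` rows by ``len(snp_ids)`` columns.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    genotypes: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.float64)
        if self.genotypes.shape[1] != len(self.snp_ids):
            raise ValueError("genotype columns must match snp_ids")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    def freq(self, snps=None) -> np.ndarray:
        idx = self._locate(snps)
        return self.genotypes[:, idx].mean(axis=0) / 2.0

    def _locate(self, snps):
        if snps is None:
            return np.arange(len(self.snp_ids))
        missing = [s for s in snps if s not in self._index]
        if missing:
            raise KeyError(f"SNPs absent from LD panel: {missing[:5]}")
        return np.array([self._index[s] for s in snps], dtype=int)

    def corr(self, snps, effect_alleles=None) -> np.ndarray:
        """LD correlation matrix for ``snps``, optionally re-signed.

        When ``effect_alleles`` is given, the dosage of SNP *i* is flipped
        wherever the caller's effect allele is the panel's other allele, so the
        returned ``r`` carries the sign convention of the caller's betas.
        """
        idx = self._locate(snps)
        x = self.genotypes[:, idx].copy()
        if effect_alleles is not None:
            for k, (j, ea) in enumerate(zip(idx, effect_alleles)):
                if ea == self.effect_allele[j]:
                    continue
                if ea == self.other_allele[j]:
                    x[:, k] = 2.0 - x[:, k]
                else:
                    raise ValueError(
                        f"allele {ea} not segregating at {self.snp_ids[j]}"
                    )
        sd = x.std(axis=0)
        if (sd == 0).any():
            bad = [str(s) for s, v in zip(np.asarray(snps), sd) if v == 0]
            raise ValueError(f"monomorphic in panel: {bad[:5]}")
        r = np.corrcoef(x, rowvar=False)
        return np.atleast_2d(r)


# ---------------------------------------------------------------------------
# GWAS "ma" files
# ---------------------------------------------------------------------------

def read_gwas_ma(path) -> pd.DataFrame:
    """Read a GWAS "ma" summary file into the canonical frame.

    Returns a DataFrame with columns :data:`REC_COLUMNS`; alleles are
    uppercased.  Rows with non-numeric or invariant-violating ``b``/``se``/``p``
    are rejected and reported (row-numbered, 1-based data rows) in
    ``frame.attrs["rejected"]``.

    Raises
    ------
    SumstatsFormatError
        If a mandatory column is missing or snp ids are duplicated.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    missing = [c for c in MA_COLUMNS if c not in raw.columns]
    if missing:
        raise SumstatsFormatError(
            f"{path}: missing mandatory column(s) {missing}"
        )
    raw = raw[MA_COLUMNS].copy()
    raw.columns = REC_COLUMNS

    rejected: list[dict] = []
    def _float(v):
        # exact (shortest-repr round-trip) parsing, unlike the fast C parser
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    num = raw[["freq", "b", "se", "p", "n"]].map(_float)
    bad_numeric = num[["b", "se", "p"]].isna().any(axis=1)
    bad_se = num["se"] <= 0
    bad_p = (num["p"] <= 0) | (num["p"] > 1)
    bad_freq = (num["freq"] < 0) | (num["freq"] > 1)
    bad = bad_numeric | bad_se.fillna(False) | bad_p.fillna(False) | bad_freq.fillna(False)
    for i in raw.index[bad]:
        if bad_numeric[i]:
            reason = "non-numeric b/se/p"
        elif bad_se[i]:
            reason = "se <= 0"
        elif bad_p[i]:
            reason = "p outside (0,1]"
        else:
            reason = "freq outside [0,1]"
        rejected.append({"row": int(i) + 1, "snp": raw.at[i, "snp"], "reason": reason})

    out = raw.loc[~bad].copy()
    out[["freq", "b", "se", "p", "n"]] = num.loc[~bad]
    if len(out) and out["n"].notna().all() and (out["n"] == out["n"].round()).all():
        out["n"] = out["n"].astype(np.int64)  # sample sizes are counts
    out["a1"] = out["a1"].str.upper()
    out["a2"] = out["a2"].str.upper()
    dup = out["snp"][out["snp"].duplicated()].unique()
    if len(dup):
        raise SumstatsFormatError(f"{path}: duplicate snp ids: {list(dup)[:10]}")
    out = out.reset_index(drop=True)
    out.attrs["rejected"] = rejected
    return out


def write_gwas_ma(frame: pd.DataFrame, path) -> None:
    """Write the canonical frame back to the "ma" layout (tab-separated)."""
    out = frame[REC_COLUMNS].copy()
    out.columns = MA_COLUMNS
    out.to_csv(path, sep="\t", index=False, na_rep=NA_SENTINEL)


def read_qtl_long(path) -> list[QTLProbe]:
    """Read long-format QTL TSV (one row per probe x variant) into probes."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "a1": str, "a2": str},
                     float_precision="round_trip")
    missing = [c for c in QTL_LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing column(s) {missing}")
    probes = []
    for probe_id, grp in df.groupby("probe", sort=True):
        first = grp.iloc[0]
        rec = grp[["snp", "chrom", "pos", "a1", "a2", "freq", "b", "se", "p"]].copy()
        rec["a1"] = rec["a1"].str.upper()
        rec["a2"] = rec["a2"].str.upper()
        probes.append(
            QTLProbe(
                probe_id=str(probe_id),
                gene_symbol=None if pd.isna(first["gene"]) else str(first["gene"]),
                chrom=str(first["chrom"]),
                probe_pos=int(first.get("probe_pos", grp["pos"].median())),
                omic=str(first["omic"]),
                tissue=str(first["tissue"]),
                ancestry=str(first["ancestry"]),
                records=rec.reset_index(drop=True),
            )
        )
    return probes


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    gwas: pd.DataFrame,
    qtl: QTLProbe,
    panel: LDPanel | None = None,
    freq_tol: float = 0.2,
) -> pd.DataFrame:
    """Align GWAS records to a probe's effect-allele convention.

    For shared SNPs where A1/A2 are swapped between the two sources the GWAS
    beta is negated and its frequency replaced by ``1 - freq``; SNPs whose
    allele sets differ outright are dropped, as are SNPs whose aligned allele
    frequencies disagree by more than ``freq_tol``.  Strand-ambiguous (A/T,
    C/G) SNPs are retained but flagged ``palindromic``.  Output rows are
    ordered by position; drops are reported in ``frame.attrs["dropped"]``.

    Raises
    ------
    ValueError
        If the two sources share no variants ("no shared variants").
    """
    q = qtl.records
    merged = gwas.merge(
        q, on="snp", how="inner", suffixes=("_gwas", "_qtl"), validate="1:1"
    )
    if merged.empty:
        raise ValueError("no shared variants")

    same = (merged["a1_gwas"] == merged["a1_qtl"]) & (merged["a2_gwas"] == merged["a2_qtl"])
    swap = (merged["a1_gwas"] == merged["a2_qtl"]) & (merged["a2_gwas"] == merged["a1_qtl"])
    mismatch = ~(same | swap)

    b_g = merged["b_gwas"].where(~swap, -merged["b_gwas"])
    f_g = merged["freq_gwas"].where(~swap, 1.0 - merged["freq_gwas"])
    freq_bad = (f_g - merged["freq_qtl"]).abs() > freq_tol

    dropped = {
        "allele_mismatch": merged.loc[mismatch, "snp"].tolist(),
        "freq_mismatch": merged.loc[~mismatch & freq_bad, "snp"].tolist(),
    }
    keep = ~(mismatch | freq_bad)

    out = pd.DataFrame(
        {
            "snp": merged["snp"],
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "a1": merged["a1_qtl"],
            "a2": merged["a2_qtl"],
            "freq": merged["freq_qtl"],
            "freq_gwas": f_g,
            "b_gwas": b_g,
            "se_gwas": merged["se_gwas"],
            "p_gwas": merged["p_gwas"],
            "n_gwas": merged.get("n"),
            "b_qtl": merged["b_qtl"],
            "se_qtl": merged["se_qtl"],
            "p_qtl": merged["p_qtl"],
            "palindromic": [
                _is_palindromic(x, y)
                for x, y in zip(merged["a1_qtl"], merged["a2_qtl"])
            ],
        }
    )[keep]
    if panel is not None:
        in_panel = out["snp"].map(lambda s: s in panel)
        dropped["absent_from_panel"] = out.loc[~in_panel, "snp"].tolist()
        out = out[in_panel]
    out = out.sort_values(["pos", "snp"], kind="mergesort").reset_index(drop=True)
    out.attrs["dropped"] = dropped
    return out


def z_to_beta_se(z, freq_a1, n):
    """Complete per-allele effect sizes from a standardized Z score.

    Implements the standard completion for panels distributing only Z scores:

        se   = 1 / sqrt(2 f (1 - f) (n + z^2))
        beta = z * se

    so ``beta / se == z`` exactly.  Vectorized over array inputs.

    Raises
    ------
    ValueError
        For monomorphic variants (``freq_a1`` of exactly 0 or 1).
    """
    z = np.asarray(z, dtype=float)
    f = np.asarray(freq_a1, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((f <= 0.0) | (f >= 1.0)):
        raise ValueError("monomorphic variant")
    if np.any(n <= 0):
        raise ValueError("sample count must be positive")
    se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * (n + z * z))
    beta = z * se
    if beta.ndim == 0:
        return float(beta), float(se)
    return beta, se


# ---------------------------------------------------------------------------
# Three-file QTL store
# ---------------------------------------------------------------------------

class QTLSerializationError(ValueError):
    pass


def serialize_qtl(probes: list[QTLProbe], out_prefix, variant_index: pd.DataFrame | None = None) -> None:
    """Write a QTL dataset as three text files.

    ``<prefix>.snps.tsv``    variant index: snp chrom pos a1 a2 freq
    ``<prefix>.probes.tsv``  probe index: probe chrom pos gene omic tissue ancestry
    ``<prefix>.effects.tsv`` effects store: probe snp b se p

    Missing effects are written as the reserved sentinel ``NA``.  When
    ``variant_index`` is supplied, every probe record must reference a variant
    present in it, else :class:`QTLSerializationError` is raised.
    """
    prefix = Path(out_prefix)
    rec_frames = []
    for pr in probes:
        r = pr.records.copy()
        r.insert(0, "probe", pr.probe_id)
        rec_frames.append(r)
    allrec = (
        pd.concat(rec_frames, ignore_index=True)
        if rec_frames
        else pd.DataFrame(columns=["probe", "snp", "chrom", "pos", "a1", "a2", "freq", "b", "se", "p"])
    )

    if variant_index is None:
        vidx = (
            allrec[["snp", "chrom", "pos", "a1", "a2", "freq"]]
            .drop_duplicates(subset="snp")
            .sort_values(["chrom", "pos", "snp"], kind="mergesort")
        )
    else:
        vidx = variant_index
        unknown = set(allrec["snp"]) - set(vidx["snp"])
        if unknown:
            raise QTLSerializationError(
                f"probe records reference variants absent from index: {sorted(unknown)[:5]}"
            )

    pidx = pd.DataFrame(
        [
            {
                "probe": pr.probe_id,
                "chrom": pr.chrom,
                "pos": pr.probe_pos,
                "gene": pr.gene_symbol,
                "omic": pr.omic,
                "tissue": pr.tissue,
                "ancestry": pr.ancestry,
            }
            for pr in probes
        ],
        columns=["probe", "chrom", "pos", "gene", "omic", "tissue", "ancestry"],
    )

    vidx.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False, na_rep=NA_SENTINEL)
    pidx.to_csv(f"{prefix}.probes.tsv", sep="\t", index=False, na_rep=NA_SENTINEL)
    allrec[["probe", "snp", "b", "se", "p"]].to_csv(
        f"{prefix}.effects.tsv", sep="\t", index=False, na_rep=NA_SENTINEL
    )


def load_qtl(prefix) -> list[QTLProbe]:
    """Reconstruct a QTL dataset written by :func:`serialize_qtl`."""
    vidx = pd.read_csv(f"{prefix}.snps.tsv", sep="\t", dtype={"chrom": str},
                       float_precision="round_trip")
    pidx = pd.read_csv(f"{prefix}.probes.tsv", sep="\t", dtype={"chrom": str})
    eff = pd.read_csv(f"{prefix}.effects.tsv", sep="\t", float_precision="round_trip")
    unknown = set(eff["snp"]) - set(vidx["snp"])
    if unknown:
        raise QTLSerializationError(
            f"effects reference variants absent from index: {sorted(unknown)[:5]}"
        )
    probes = []
    for _, row in pidx.iterrows():
        sub = eff[eff["probe"] == row["probe"]]
        rec = sub.merge(vidx, on="snp", how="left")[
            ["snp", "chrom", "pos", "a1", "a2", "freq", "b", "se", "p"]
        ].reset_index(drop=True)
        probes.append(
            QTLProbe(
                probe_id=str(row["probe"]),
                gene_symbol=None if pd.isna(row["gene"]) else str(row["gene"]),
                chrom=str(row["chrom"]),
                probe_pos=int(row["pos"]),
                omic=str(row["omic"]),
                tissue=str(row["tissue"]),
                ancestry=str(row["ancestry"]),
                records=rec,
            )
        )
    return probes


# ---------------------------------------------------------------------------
# LD panel text store
# ---------------------------------------------------------------------------

def write_ld_panel(panel: LDPanel, prefix) -> None:
    meta = pd.DataFrame(
        {
            "snp": panel.snp_ids,
            "chrom": panel.chrom,
            "pos": panel.pos,
            "a1": panel.effect_allele,
            "a2": panel.other_allele,
        }
    )
    meta.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)
    np.savetxt(f"{prefix}.geno.tsv", panel.genotypes, fmt="%d", delimiter="\t")


def read_ld_panel(prefix) -> LDPanel:
    meta = pd.read_csv(f"{prefix}.snps.tsv", sep="\t", dtype={"chrom": str})
    geno = np.loadtxt(f"{prefix}.geno.tsv", delimiter="\t", ndmin=2)
    return LDPanel(
        snp_ids=meta["snp"].to_numpy(dtype=object),
        chrom=meta["chrom"].to_numpy(dtype=object),
        pos=meta["pos"].to_numpy(dtype=int),
        effect_allele=meta["a1"].to_numpy(dtype=object),
        other_allele=meta["a2"].to_numpy(dtype=object),
        genotypes=geno,
    )
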