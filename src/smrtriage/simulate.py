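"""Synthetic inputs for the whole pipeline.

Everything the analysis consumes can be generated here: LD reference panels
(haplotypes from a latent AR(1) Gaussian threshold model), GWAS and cis-QTL
summary statistics under pleiotropy / linkage / null scenarios (individual-
level phenotypes are simulated and reduced to per-SNP marginal regressions, so
the LD-induced correlation structure that HEIDI and multi-SNP SMR depend on is
preserved), and negative-binomial single-nucleus counts matrices.  Snapshot
fixtures (annotation, druggability, indications, interaction edges) live in
:mod:`smrtriage.fixtures`.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .sumstats import LDPanel, QTLProbe

__all__ = [
    "ScenarioSpec",
    "simulate_ld_panel",
    "simulate_scenario",
    "simulate_replicates",
    "ReplicateSet",
    "simulate_counts",
    "simulate_annotation",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative conditions for one GWAS x QTL scenario.

    kind
        ``pleiotropy`` (one causal SNP affects the exposure with ``b_zx`` and
        the outcome through it with per-allele effect ``b_zx * b_xy``),
        ``linkage`` (SNP A affects the exposure only; a distinct SNP B in LD
        ``r_link`` with A affects the outcome only), or ``null`` (exposure
        effects only, no SNP -> outcome effect).
    m_snps, ld_rho
        Cis-region size and latent AR(1) correlation of the panel/cohorts.
    n_gwas, n_qtl
        Outcome and exposure cohort sizes.
    """

    kind: str = "pleiotropy"
    m_snps: int = 30
    ld_rho: float = 0.7
    b_zx: float = 0.3
    b_xy: float = 0.2
    r_link: float = 0.7
    n_gwas: int = 50_000
    n_qtl: int = 5_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_index: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in {"pleiotropy", "linkage", "null"}:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if not (-1.0 < self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in (-1, 1)")

    @property
    def causal(self) -> int:
        return self.m_snps // 2 if self.causal_index is None else self.causal_index


def _latent_ar1(n: int, m: int, rho: float, rng) -> np.ndarray:
    """n x m standard-normal draws with AR(1) column correlation rho."""
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    if m > 1:
        innov = rng.standard_normal((n, m - 1)) * np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    return z


def _draw_genotypes(n_ind: int, mafs: np.ndarray, rho: float, rng) -> np.ndarray:
    """Diploid dosages: two threshold-model haplotypes per individual."""
    m = len(mafs)
    thresh = norm.ppf(mafs)
    h1 = (_latent_ar1(n_ind, m, rho, rng) < thresh).astype(np.float64)
    h2 = (_latent_ar1(n_ind, m, rho, rng) < thresh).astype(np.float64)
    return h1 + h2


def simulate_ld_panel(
    m_snps: int,
    n_hap: int = 1000,
    ld_rho: float = 0.7,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    chrom: str = "1",
    pos_start: int = 1_000_000,
    spacing: int = 25_000,
) -> LDPanel:
    """Simulate a hard-call LD reference panel.

    Haplotypes follow a latent AR(1) Gaussian threshold model, so realized
    adjacent-SNP correlation is a deterministic (attenuating) function of
    ``ld_rho``; ``n_hap`` counts haplotypes (two per diploid sample).
    """
    if m_snps < 1:
        raise ValueError("m_snps must be >= 1")
    if n_hap < 50:
        raise ValueError("n_hap must be >= 50")
    lo, hi = maf_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("degenerate maf_range")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=m_snps)
    n_ind = n_hap // 2
    geno = _draw_genotypes(n_ind, mafs, ld_rho, rng)
    allele_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(m_snps)])
    panel = LDPanel(
        snp_ids=np.array([f"rs{i + 1}" for i in range(m_snps)], dtype=object),
        chrom=np.full(m_snps, chrom, dtype=object),
        pos=pos_start + spacing * np.arange(m_snps),
        effect_allele=_BASES[allele_idx[:, 0]],
        other_allele=_BASES[allele_idx[:, 1]],
        genotypes=geno,
    )
    # generative parameters, so cohort genotypes can be drawn from the same model
    panel.sim_maf = mafs
    panel.sim_rho = ld_rho
    return panel


def _marginal_stats(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-SNP simple-regression beta/se/p of y on each genotype column."""
    n, m = G.shape
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    ssg = np.einsum("ij,ij->j", Gc, Gc)
    b = (Gc.T @ yc) / ssg
    ssy = float(yc @ yc)
    resid = np.maximum(ssy - b**2 * ssg, 0.0) / (n - 2)
    se = np.sqrt(resid / ssg)
    z2 = (b / se) ** 2
    p = chi2.sf(z2, df=1)
    return b, se, np.clip(p, 1e-300, 1.0)


def _noise_sd(explained: float) -> float:
    if explained >= 1.0:
        raise ValueError("requested effects exceed unit phenotype variance")
    return float(np.sqrt(1.0 - explained))


def _scenario_effects(spec: ScenarioSpec, panel: LDPanel) -> tuple[int, int | None]:
    """(exposure causal index, outcome causal index or None)."""
    a = spec.causal
    if spec.kind == "pleiotropy":
        return a, a
    if spec.kind == "null":
        return a, None
    # linkage: pick the distinct SNP whose panel r with A is closest to r_link
    R = panel.corr(list(panel.snp_ids))
    r_to_a = R[a].copy()
    r_to_a[a] = np.inf
    b = int(np.argmin(np.abs(np.abs(r_to_a) - spec.r_link)))
    return a, b


def _cohort_genotypes(spec: ScenarioSpec, panel: LDPanel, n: int, rng) -> np.ndarray:
    mafs = getattr(panel, "sim_maf", None)
    rho = getattr(panel, "sim_rho", spec.ld_rho)
    if mafs is None:
        mafs = panel.freq()
    return _draw_genotypes(n, np.asarray(mafs), rho, rng)


def _gwas_signal(spec: ScenarioSpec, G: np.ndarray, outcome_idx: int | None):
    if outcome_idx is None:
        return 0.0, 0.0
    eff = spec.b_zx * spec.b_xy
    g = G[:, outcome_idx]
    return eff * (g - g.mean()), eff**2 * g.var()


def simulate_scenario(spec: ScenarioSpec, panel: LDPanel) -> tuple[pd.DataFrame, QTLProbe]:
    """One synthetic dataset: GWAS records plus a cis-QTL probe.

    Individual-level phenotypes (unit total variance) are simulated for
    separate outcome and exposure cohorts and reduced to per-SNP marginal
    summary statistics.  Reproducible bit-for-bit under ``spec.seed``.
    """
    if spec.m_snps > len(panel.snp_ids):
        raise ValueError("panel smaller than requested scenario")
    rng = np.random.default_rng(spec.seed)
    a, b_idx = _scenario_effects(spec, panel)

    Gq = _cohort_genotypes(spec, panel, spec.n_qtl, rng)
    gq = Gq[:, a]
    expl_x = spec.b_zx**2 * gq.var()
    x = spec.b_zx * (gq - gq.mean()) + _noise_sd(expl_x) * rng.standard_normal(spec.n_qtl)
    bx, sex, px = _marginal_stats(Gq, x)

    Gg = _cohort_genotypes(spec, panel, spec.n_gwas, rng)
    sig, expl_y = _gwas_signal(spec, Gg, b_idx)
    y = sig + _noise_sd(expl_y) * rng.standard_normal(spec.n_gwas)
    bg, seg, pg = _marginal_stats(Gg, y)

    meta = pd.DataFrame(
        {
            "snp": panel.snp_ids,
            "chrom": panel.chrom,
            "pos": panel.pos,
            "a1": panel.effect_allele,
            "a2": panel.other_allele,
        }
    )
    gwas = meta[["snp", "a1", "a2"]].copy()
    gwas["freq"] = Gg.mean(axis=0) / 2.0
    gwas["b"] = bg
    gwas["se"] = seg
    gwas["p"] = pg
    gwas["n"] = spec.n_gwas

    rec = meta.copy()
    rec["freq"] = Gq.mean(axis=0) / 2.0
    rec["b"] = bx
    rec["se"] = sex
    rec["p"] = px
    probe = QTLProbe(
        probe_id="probe1",
        gene_symbol="GENE1",
        chrom=str(panel.chrom[0]),
        probe_pos=int(panel.pos[a]),
        omic="eQTL",
        tissue="whole-blood",
        records=rec,
    )
    return gwas, probe


@dataclass
class ReplicateSet:
    """Marginal summary statistics for many phenotype replicates.

    Cohort genotypes are drawn once; phenotypes are redrawn per replicate, so
    arrays are (n_reps, m_snps).  ``to_frames(i)`` materializes replicate
    ``i`` as the (gwas frame, probe) pair the model API consumes.
    """

    spec: ScenarioSpec
    panel: LDPanel
    b_g: np.ndarray
    se_g: np.ndarray
    b_x: np.ndarray
    se_x: np.ndarray
    freq_gwas: np.ndarray
    freq_qtl: np.ndarray

    @property
    def n_reps(self) -> int:
        return self.b_g.shape[0]

    def to_frames(self, i: int) -> tuple[pd.DataFrame, QTLProbe]:
        panel, spec = self.panel, self.spec
        meta = pd.DataFrame(
            {
                "snp": panel.snp_ids,
                "chrom": panel.chrom,
                "pos": panel.pos,
                "a1": panel.effect_allele,
                "a2": panel.other_allele,
            }
        )
        gwas = meta[["snp", "a1", "a2"]].copy()
        gwas["freq"] = self.freq_gwas
        gwas["b"] = self.b_g[i]
        gwas["se"] = self.se_g[i]
        gwas["p"] = np.clip(chi2.sf((self.b_g[i] / self.se_g[i]) ** 2, 1), 1e-300, 1.0)
        gwas["n"] = spec.n_gwas
        rec = meta.copy()
        rec["freq"] = self.freq_qtl
        rec["b"] = self.b_x[i]
        rec["se"] = self.se_x[i]
        rec["p"] = np.clip(chi2.sf((self.b_x[i] / self.se_x[i]) ** 2, 1), 1e-300, 1.0)
        probe = QTLProbe(
            probe_id="probe1",
            gene_symbol="GENE1",
            chrom=str(panel.chrom[0]),
            probe_pos=int(panel.pos[spec.causal]),
            omic="eQTL",
            tissue="whole-blood",
            records=rec,
        )
        return gwas, probe


def _batch_marginals(G: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-SNP regressions of each Y column on each G column."""
    n = G.shape[0]
    Gc = G - G.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    ssg = np.einsum("ij,ij->j", Gc, Gc)
    B = (Gc.T @ Yc) / ssg[:, None]          # m x reps
    ssy = np.einsum("ij,ij->j", Yc, Yc)     # reps
    resid = np.maximum(ssy[None, :] - B**2 * ssg[:, None], 0.0) / (n - 2)
    SE = np.sqrt(resid / ssg[:, None])
    return B.T, SE.T


def simulate_replicates(
    spec: ScenarioSpec,
    panel: LDPanel,
    n_reps: int,
    seed: int | None = None,
    chunk: int = 100,
) -> ReplicateSet:
    """Many phenotype replicates over fixed cohort genotypes.

    Used by the calibration suites: type-I error and parameter recovery are
    assessed over phenotype randomness conditional on one genotype draw,
    under which the marginal tests are exact.  Far cheaper than redrawing
    cohorts, with arrays laid out (replicate, SNP).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    a, b_idx = _scenario_effects(spec, panel)

    Gq = _cohort_genotypes(spec, panel, spec.n_qtl, rng)
    Gg = _cohort_genotypes(spec, panel, spec.n_gwas, rng)
    gq = Gq[:, a]
    xsig = spec.b_zx * (gq - gq.mean())
    xnoise = _noise_sd(spec.b_zx**2 * gq.var())
    ysig, expl_y = _gwas_signal(spec, Gg, b_idx)
    ynoise = _noise_sd(expl_y)

    m = spec.m_snps
    b_x = np.empty((n_reps, m)); se_x = np.empty((n_reps, m))
    b_g = np.empty((n_reps, m)); se_g = np.empty((n_reps, m))
    for lo in range(0, n_reps, chunk):
        hi = min(lo + chunk, n_reps)
        k = hi - lo
        X = xsig[:, None] + xnoise * rng.standard_normal((spec.n_qtl, k))
        b_x[lo:hi], se_x[lo:hi] = _batch_marginals(Gq, X)
        Y = (ysig[:, None] if np.ndim(ysig) else ysig) + ynoise * rng.standard_normal(
            (spec.n_gwas, k)
        )
        b_g[lo:hi], se_g[lo:hi] = _batch_marginals(Gg, Y)
    return ReplicateSet(
        spec=spec,
        panel=panel,
        b_g=b_g,
        se_g=se_g,
        b_x=b_x,
        se_x=se_x,
        freq_gwas=Gg.mean(axis=0) / 2.0,
        freq_qtl=Gq.mean(axis=0) / 2.0,
    )


# ---------------------------------------------------------------------------
# Single-nucleus counts
# ---------------------------------------------------------------------------

def simulate_counts(
    structure: pd.DataFrame,
    cells_per_type: dict[str, int],
    dispersion: float = 2.0,
    exon_lengths: pd.Series | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Negative-binomial counts with gene x cell-type means from ``structure``.

    ``structure`` is genes x cell types of NB means (var = mu + mu^2/size with
    ``size = dispersion``).  Returns ``(counts, cell_type, exon_length)``;
    exon lengths default to a reproducible uniform draw in 500-3000 bp.
    """
    rng = np.random.default_rng(seed)
    genes = structure.index
    cols, types = [], []
    blocks = []
    for ct in structure.columns:
        k = cells_per_type.get(ct, 0)
        if k <= 0:
            continue
        mu = structure[ct].to_numpy(dtype=float)[:, None] * np.ones((1, k))
        p = dispersion / (dispersion + np.maximum(mu, 1e-12))
        blocks.append(rng.negative_binomial(dispersion, p))
        cols.extend(f"{ct}_{i + 1}" for i in range(k))
        types.extend([ct] * k)
    counts = pd.DataFrame(
        np.hstack(blocks) if blocks else np.empty((len(genes), 0), dtype=int),
        index=genes,
        columns=cols,
    )
    cell_type = pd.Series(types, index=cols, name="cell_type")
    if exon_lengths is None:
        exon_lengths = pd.Series(
            rng.integers(500, 3001, size=len(genes)), index=genes, name="exon_length"
        )
    return counts, cell_type, exon_lengths


def simulate_annotation(
    genes,
    chrom: str = "1",
    start: int = 1_000_000,
    spacing: int = 1_000_000,
    protein_coding: bool = True,
) -> pd.DataFrame:
    """Minimal gene annotation table (symbol, span, coding flag) for tests."""
    genes = list(genes)
    starts = start + spacing * np.arange(len(genes))
    return pd.DataFrame(
        {
            "gene": genes,
            "chrom": chrom,
            "start": starts,
            "end": starts + 10_000,
            "protein_coding": protein_coding,
        }
    )
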