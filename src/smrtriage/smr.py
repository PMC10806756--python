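"""Core SMR statistics: single-SNP SMR, multi-SNP SMR and the HEIDI test.

Summary-data Mendelian randomization treats the top cis-QTL SNP of a probe as
an instrument for the molecular exposure and asks whether the exposure and the
outcome share a causal variant.  With z_g = b_GWAS/se_GWAS and
z_x = b_QTL/se_QTL at the instrument, the 1-df test statistic is

    T_SMR = z_g^2 z_x^2 / (z_g^2 + z_x^2),

the Wald ratio estimate is beta_SMR = b_GWAS / b_QTL, and its standard error
follows from the delta method.  HEIDI asks whether the ratio estimates at
surrounding cis SNPs are mutually consistent (pleiotropy: one shared causal
variant) or heterogeneous (linkage: distinct variants in LD), using LD
correlations from a reference panel.  The multi-SNP SMR test sums the per-SNP
statistics over a near-independent instrument set and refers the sum to a
weighted chi-square tail.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._quadform import weighted_chisq_sf
from .sumstats import LDPanel, QTLProbe, harmonize

__all__ = [
    "SMRConfig",
    "SMRStat",
    "smr_single",
    "select_instruments",
    "heidi",
    "heidi_components",
    "smr_multi",
    "SMRModel",
    "SMRResults",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "probe", "gene", "disease", "omic_tissue", "ancestry", "chrom", "probe_pos",
    "topSNP", "A1", "A2", "freq",
    "b_GWAS", "se_GWAS", "p_GWAS",
    "b_eQTL", "se_eQTL", "p_eQTL",
    "b_SMR", "se_SMR", "p_SMR", "p_SMR_multi", "p_HEIDI", "nsnp_HEIDI",
]


@dataclass(frozen=True)
class SMRConfig:
    """Engine defaults, mirroring the reference implementation's defaults.

    cis_window_kb
        Window around the probe for instrument discovery (2,000 kb).
    p_instrument
        QTL significance required of the top instrument (5e-8).
    heidi_window_kb / heidi_max_snps / heidi_p_qtl
        HEIDI consumes at most the top 20 QTL SNPs within 500 kb passing a
        laxer eligibility threshold (1.57e-3).
    heidi_r2_min / heidi_r2_max
        Non-top HEIDI SNPs must have r^2 with the top SNP inside [0.05, 0.9].
    heidi_min_snps
        Minimum non-top SNPs for a reported HEIDI p (3); otherwise missing.
    prune_r2_max
        Multi-SNP SMR prunes instruments to pairwise r^2 below 0.9.
    """

    cis_window_kb: float = 2000.0
    p_instrument: float = 5e-8
    heidi_window_kb: float = 500.0
    heidi_max_snps: int = 20
    heidi_p_qtl: float = 1.57e-3
    heidi_r2_min: float = 0.05
    heidi_r2_max: float = 0.9
    heidi_min_snps: int = 3
    prune_r2_max: float = 0.9
    freq_tol: float = 0.2
    seed: int = 0


@dataclass(frozen=True)
class SMRStat:
    beta_smr: float
    se_smr: float
    t_smr: float
    p_smr: float


def smr_single(b_g: float, se_g: float, b_x: float, se_x: float) -> SMRStat:
    """Single-instrument SMR statistic and Wald ratio estimate.

    ``b_g``/``se_g`` are the outcome (GWAS) effect and standard error at the
    instrument; ``b_x``/``se_x`` the exposure (QTL) ones.  ``b_x`` must be
    nonzero.  ``b_g == 0`` yields beta_SMR = 0 with se_SMR = se_g/|b_x|
    (continuity convention) and p = 1.
    """
    if se_g <= 0 or se_x <= 0:
        raise ValueError("standard errors must be positive")
    if b_x == 0:
        raise ValueError("undefined ratio: exposure effect is zero")
    z_g = b_g / se_g
    z_x = b_x / se_x
    t = (z_g**2 * z_x**2) / (z_g**2 + z_x**2)
    p = float(chi2.sf(t, df=1))
    beta = b_g / b_x
    # delta-method se in a form stable as b_g -> 0 (where it tends to se_g/|b_x|)
    se = float(np.hypot(se_g / b_x, b_g * se_x / (b_x * b_x)))
    return SMRStat(beta_smr=float(beta), se_smr=se, t_smr=float(t), p_smr=p)


class NoInstrumentError(ValueError):
    """No cis SNP qualifies as an instrument for this probe."""


def select_instruments(
    aligned: pd.DataFrame,
    probe_pos: int,
    window_kb: float = 2000.0,
    p_instrument: float = 5e-8,
) -> pd.DataFrame:
    """Cis SNPs qualifying as instruments, best QTL p first.

    ``aligned`` is a harmonized frame (see :func:`smrtriage.sumstats.harmonize`).
    SNPs must lie within ``window_kb`` of the probe and have QTL p below
    ``p_instrument``; ties in p break by position for determinism.
    """
    half = window_kb * 1000.0
    ok = (aligned["pos"] - probe_pos).abs() <= half
    ok &= aligned["p_qtl"] < p_instrument
    sel = aligned[ok].sort_values(["p_qtl", "pos"], kind="mergesort")
    if sel.empty:
        raise NoInstrumentError("no instrument")
    return sel.reset_index(drop=True)


def _heidi_covariance(b_g, se_g, b_x, se_x, R):
    """Delta-method covariance of d_i = b_g_i/b_x_i - b_g_0/b_x_0 (top = 0)."""
    m = len(b_g)
    d = b_g[1:] / b_x[1:] - b_g[0] / b_x[0]
    # Jacobian wrt the stacked vector (b_g_0..m-1, b_x_0..m-1)
    J = np.zeros((m - 1, 2 * m))
    for i in range(1, m):
        J[i - 1, i] = 1.0 / b_x[i]
        J[i - 1, 0] = -1.0 / b_x[0]
        J[i - 1, m + i] = -b_g[i] / b_x[i] ** 2
        J[i - 1, m] = b_g[0] / b_x[0] ** 2
    sig = np.zeros((2 * m, 2 * m))
    sig[:m, :m] = R * np.outer(se_g, se_g)
    sig[m:, m:] = R * np.outer(se_x, se_x)
    V = J @ sig @ J.T
    return d, V


def heidi_components(
    aligned: pd.DataFrame,
    probe_pos: int,
    panel: LDPanel,
    config: SMRConfig = SMRConfig(),
) -> tuple[float, np.ndarray | None, int]:
    """HEIDI statistic, null eigenvalues and SNP count (see :func:`heidi`).

    Returns ``(T, eigenvalues, n_used)``; ``T`` is NaN and the eigenvalues
    ``None`` when fewer than ``config.heidi_min_snps`` usable SNPs remain.
    Under the single-shared-causal-variant null, T is distributed as the
    eigenvalue-weighted sum of 1-df chi-squares.
    """
    half = config.heidi_window_kb * 1000.0
    cand = aligned[
        ((aligned["pos"] - probe_pos).abs() <= half)
        & (aligned["p_qtl"] < config.heidi_p_qtl)
    ].sort_values(["p_qtl", "pos"], kind="mergesort")
    if cand.empty:
        return float("nan"), None, 0
    cand = cand.head(config.heidi_max_snps)

    top = cand.iloc[0]
    rest = cand.iloc[1:]
    if rest.empty:
        return float("nan"), None, 0

    snps = [top["snp"]] + rest["snp"].tolist()
    alleles = [top["a1"]] + rest["a1"].tolist()
    R = panel.corr(snps, alleles)
    r2_top = R[0, 1:] ** 2
    keep = (r2_top >= config.heidi_r2_min) & (r2_top <= config.heidi_r2_max)
    rest = rest[keep]
    if len(rest) < config.heidi_min_snps:
        return float("nan"), None, 0

    sub = pd.concat([top.to_frame().T, rest])
    idx = [0] + list(np.where(keep)[0] + 1)
    R = R[np.ix_(idx, idx)]
    b_g = sub["b_gwas"].to_numpy(dtype=float)
    se_g = sub["se_gwas"].to_numpy(dtype=float)
    b_x = sub["b_qtl"].to_numpy(dtype=float)
    se_x = sub["se_qtl"].to_numpy(dtype=float)

    while True:
        d, V = _heidi_covariance(b_g, se_g, b_x, se_x, R)
        sd = np.sqrt(np.diag(V))
        C = V / np.outer(sd, sd)
        eig = np.linalg.eigvalsh(C)
        if eig.min() > 1e-8:
            break
        # near-singular: drop the non-top SNP most collinear with the rest
        m = R.shape[0]
        if m - 1 <= config.heidi_min_snps:
            return float("nan"), None, 0
        offdiag = np.abs(R - np.eye(m))
        worst = int(np.argmax(offdiag[1:, :].max(axis=1))) + 1
        sel = [j for j in range(m) if j != worst]
        R = R[np.ix_(sel, sel)]
        b_g, se_g = b_g[sel], se_g[sel]
        b_x, se_x = b_x[sel], se_x[sel]

    z = d / sd
    T = float(np.sum(z**2))
    return T, np.clip(eig, 0.0, None), int(len(d))


def heidi(
    aligned: pd.DataFrame,
    probe_pos: int,
    panel: LDPanel,
    config: SMRConfig = SMRConfig(),
) -> tuple[float, int]:
    """Heterogeneity-in-dependent-instruments test at one probe.

    Returns ``(p_heidi, n_used)`` where ``n_used`` counts the non-top SNPs
    entering the heterogeneity sum; ``p_heidi`` is NaN when fewer than
    ``config.heidi_min_snps`` usable SNPs remain.

    The top SNP is the best-QTL-p instrument; candidate SNPs are the top
    ``heidi_max_snps`` QTL SNPs within ``heidi_window_kb`` of the probe with
    QTL p below ``heidi_p_qtl`` and r^2 to the top SNP inside
    [``heidi_r2_min``, ``heidi_r2_max``].  Differences of Wald ratios against
    the top SNP are standardized with an LD-aware delta-method covariance and
    their squared sum is referred to an eigenvalue-weighted chi-square tail.
    """
    T, eig, n_used = heidi_components(aligned, probe_pos, panel, config)
    if eig is None:
        return float("nan"), 0
    return weighted_chisq_sf(T, eig, seed=config.seed), n_used


def _prune(instruments: pd.DataFrame, panel: LDPanel, r2_max: float) -> pd.DataFrame:
    """Greedy LD pruning keeping the best QTL p in each clash."""
    snps = instruments["snp"].tolist()
    R = panel.corr(snps, instruments["a1"].tolist())
    kept: list[int] = []
    for i in range(len(snps)):
        if all(R[i, j] ** 2 < r2_max for j in kept):
            kept.append(i)
    return instruments.iloc[kept]


def smr_multi(
    instruments: pd.DataFrame,
    panel: LDPanel,
    config: SMRConfig = SMRConfig(),
) -> float:
    """Multi-SNP SMR p-value over a pruned near-independent instrument set.

    Instruments (rows of a harmonized frame, best p first) are pruned to
    pairwise r^2 < ``prune_r2_max``; the per-SNP SMR statistics are summed and
    the sum referred to a weighted chi-square tail whose weights are the
    eigenvalues of the retained SNPs' LD correlation matrix.  With a single
    retained instrument this reduces exactly to the single-SNP p.
    """
    if instruments.empty:
        raise NoInstrumentError("no instrument")
    kept = _prune(instruments, panel, config.prune_r2_max)
    stats = [
        smr_single(r["b_gwas"], r["se_gwas"], r["b_qtl"], r["se_qtl"])
        for _, r in kept.iterrows()
    ]
    if len(stats) == 1:
        return stats[0].p_smr
    T = float(sum(s.t_smr for s in stats))
    R = panel.corr(kept["snp"].tolist(), kept["a1"].tolist())
    eig = np.clip(np.linalg.eigvalsh(R), 0.0, None)
    return weighted_chisq_sf(T, eig, seed=config.seed)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class SMRModel:
    """SMR analysis of one GWAS against a cis-QTL dataset.

    Parameters
    ----------
    gwas : DataFrame
        Canonical GWAS frame (see :func:`smrtriage.sumstats.read_gwas_ma`).
    qtl : QTLProbe or list of QTLProbe
        Exposure dataset.
    panel : LDPanel
        Reference genotypes for LD; must cover every SNP HEIDI/multi-SNP use.
    disease : str
        Outcome label carried into the results table.
    config : SMRConfig
    """

    def __init__(self, gwas, qtl, panel, disease="trait", config=None):
        self.gwas = gwas
        self.qtl = [qtl] if isinstance(qtl, QTLProbe) else list(qtl)
        self.panel = panel
        self.disease = disease
        self.config = config or SMRConfig()

    def fit(self) -> "SMRResults":
        """Run SMR + HEIDI + multi-SNP SMR for every probe with an instrument.

        Probes without a qualifying instrument (or with no shared variants)
        are skipped and logged; results are ordered deterministically by
        (disease, omic_tissue, chrom, probe_pos).
        """
        cfg = self.config
        rows = []
        skipped = []
        for probe in self.qtl:
            try:
                aligned = harmonize(self.gwas, probe, self.panel, cfg.freq_tol)
            except ValueError as exc:
                skipped.append((probe.probe_id, str(exc)))
                continue
            try:
                inst = select_instruments(
                    aligned, probe.probe_pos, cfg.cis_window_kb, cfg.p_instrument
                )
            except NoInstrumentError:
                skipped.append((probe.probe_id, "no instrument"))
                continue
            top = inst.iloc[0]
            stat = smr_single(top["b_gwas"], top["se_gwas"], top["b_qtl"], top["se_qtl"])
            p_multi = smr_multi(inst, self.panel, cfg)
            p_heidi, n_heidi = heidi(aligned, probe.probe_pos, self.panel, cfg)
            rows.append(
                {
                    "probe": probe.probe_id,
                    "gene": probe.gene_symbol,
                    "disease": self.disease,
                    "omic_tissue": probe.omic_tissue,
                    "ancestry": probe.ancestry,
                    "chrom": probe.chrom,
                    "probe_pos": probe.probe_pos,
                    "topSNP": top["snp"],
                    "A1": top["a1"],
                    "A2": top["a2"],
                    "freq": top["freq"],
                    "b_GWAS": top["b_gwas"],
                    "se_GWAS": top["se_gwas"],
                    "p_GWAS": top["p_gwas"],
                    "b_eQTL": top["b_qtl"],
                    "se_eQTL": top["se_qtl"],
                    "p_eQTL": top["p_qtl"],
                    "b_SMR": stat.beta_smr,
                    "se_SMR": stat.se_smr,
                    "p_SMR": stat.p_smr,
                    "p_SMR_multi": p_multi,
                    "p_HEIDI": p_heidi,
                    "nsnp_HEIDI": n_heidi,
                }
            )
        frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        if len(frame):
            frame = frame.sort_values(
                ["disease", "omic_tissue", "chrom", "probe_pos"], kind="mergesort"
            ).reset_index(drop=True)
        return SMRResults(frame, skipped, self.config)


class SMRResults:
    """Results of :meth:`SMRModel.fit`.

    Attributes
    ----------
    frame : DataFrame
        One row per probe with the reference tool's column set plus labels.
    skipped : list of (probe_id, reason)
    """

    def __init__(self, frame: pd.DataFrame, skipped, config: SMRConfig):
        self.frame = frame
        self.skipped = list(skipped)
        self.config = config

    @property
    def direction(self) -> pd.Series:
        """Sign of beta_SMR per probe (+1/-1)."""
        return np.sign(self.frame["b_SMR"]).astype(int)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA")

    def summary(self) -> str:
        buf = io.StringIO()
        f = self.frame
        buf.write("SMR results\n")
        buf.write("=" * 64 + "\n")
        buf.write(f"probes tested: {len(f)}   skipped: {len(self.skipped)}\n")
        if len(f):
            buf.write(
                f"min p_SMR_multi: {f['p_SMR_multi'].min():.3g} "
                f"({f.loc[f['p_SMR_multi'].idxmin(), 'probe']})\n"
            )
            buf.write(f"probes with HEIDI p: {f['p_HEIDI'].notna().sum()}\n")
            cols = ["probe", "gene", "topSNP", "b_SMR", "p_SMR", "p_SMR_multi", "p_HEIDI"]
            buf.write(f[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
            buf.write("\n")
        return buf.getvalue()

    def __repr__(self):
        return f"<SMRResults: {len(self.frame)} probes, {len(self.skipped)} skipped>"
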