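"""Single-SNP SMR, HEIDI, multi-SNP SMR and the Model/Results orchestration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from smrtriage._quadform import weighted_chisq_sf
from smrtriage.simulate import ScenarioSpec, simulate_scenario
from smrtriage.smr import (
    NoInstrumentError,
    SMRConfig,
    SMRModel,
    heidi,
    heidi_components,
    select_instruments,
    smr_multi,
    smr_single,
)
from smrtriage.sumstats import harmonize


class TestSmrSingle:
    def test_null_numerator(self):
        s = smr_single(0.0, 0.1, 0.5, 0.05)
        assert s.t_smr == 0.0
        assert s.p_smr == 1.0
        assert s.beta_smr == 0.0
        assert s.se_smr == pytest.approx(0.1 / 0.5)

    def test_known_statistic(self):
        # z_g=2, z_x=4 -> T = 64/20 = 3.2
        s = smr_single(2.0, 1.0, 4.0, 1.0)
        assert s.t_smr == pytest.approx(3.2)
        assert s.p_smr == pytest.approx(chi2.sf(3.2, 1))

    @pytest.mark.parametrize("z", [0.5, 2.0, 7.5])
    def test_equal_z_symmetry(self, z):
        s = smr_single(z, 1.0, z, 1.0)
        assert s.t_smr == pytest.approx(z * z / 2)

    def test_delta_method_se(self):
        s = smr_single(0.2, 0.05, 0.5, 0.02)
        expect = abs(0.2 / 0.5) * np.sqrt((0.05 / 0.2) ** 2 + (0.02 / 0.5) ** 2)
        assert s.se_smr == pytest.approx(expect)

    def test_zero_exposure_errors(self):
        with pytest.raises(ValueError, match="ratio"):
            smr_single(0.1, 0.05, 0.0, 0.02)

    @settings(max_examples=100, deadline=None)
    @given(
        b_g=st.floats(-2, 2),
        c=st.floats(0.01, 100),
        b_x=st.floats(0.05, 2),
    )
    def test_scale_invariance(self, b_g, c, b_x):
        a = smr_single(b_g, 0.1, b_x, 0.05)
        b = smr_single(c * b_g, c * 0.1, b_x, 0.05)
        assert b.t_smr == pytest.approx(a.t_smr, rel=1e-9, abs=1e-12)
        assert b.p_smr == pytest.approx(a.p_smr, rel=1e-9, abs=1e-12)


def _aligned(rows):
    return pd.DataFrame(rows)


def _row(snp, pos, p_qtl, b_g=0.01, se_g=0.005, b_x=0.5, se_x=0.05, a1="A"):
    return dict(
        snp=snp, chrom="1", pos=pos, a1=a1, a2="G", freq=0.3, freq_gwas=0.3,
        b_gwas=b_g, se_gwas=se_g, p_gwas=0.5, n_gwas=1000,
        b_qtl=b_x, se_qtl=se_x, p_qtl=p_qtl, palindromic=False,
    )


class TestSelectInstruments:
    def test_sort_and_filter(self):
        al = _aligned(
            [
                _row("rs1", 1_000_000, 1e-9),
                _row("rs2", 1_001_000, 1e-12),
                _row("rs3", 1_002_000, 1e-3),
                _row("rs4", 1_003_000, 0.5),
                _row("rs5", 1_004_000, 1e-8 * 0.9),
            ]
        )
        sel = select_instruments(al, 1_000_000)
        assert sel["snp"].tolist() == ["rs2", "rs1", "rs5"]

    def test_window_rule(self):
        al = _aligned(
            [_row("rs1", 1_000_000, 1e-12), _row("rs2", 1_000_000 + 600_000, 1e-15)]
        )
        sel = select_instruments(al, 1_000_000, window_kb=500)
        assert sel["snp"].tolist() == ["rs1"]

    def test_no_instrument(self):
        al = _aligned([_row("rs1", 1_000_000, 1e-3)])
        with pytest.raises(NoInstrumentError):
            select_instruments(al, 1_000_000)


def _panel_aligned(panel, b_xy=0.0, strong=True, n_snps=None):
    """Aligned frame over panel SNPs whose ratios all equal b_xy exactly."""
    n = n_snps or len(panel.snp_ids)
    rows = []
    for i in range(n):
        b_x = 0.5 if strong else 0.01
        rows.append(
            dict(
                snp=panel.snp_ids[i], chrom=panel.chrom[i], pos=int(panel.pos[i]),
                a1=panel.effect_allele[i], a2=panel.other_allele[i],
                freq=0.3, freq_gwas=0.3,
                b_gwas=b_xy * b_x, se_gwas=0.004, p_gwas=0.5, n_gwas=1000,
                b_qtl=b_x, se_qtl=0.01, p_qtl=1e-20 * (i + 1),
                palindromic=False,
            )
        )
    return _aligned(rows)


class TestHeidi:
    def test_identical_ratios_give_unit_p(self, panel):
        al = _panel_aligned(panel, b_xy=0.2)
        p, n_used = heidi(al, int(panel.pos[0]), panel)
        assert p == 1.0
        assert n_used >= 3

    def test_top_snp_only_gives_missing(self, panel):
        al = _panel_aligned(panel, b_xy=0.2, n_snps=1)
        p, n_used = heidi(al, int(panel.pos[0]), panel)
        assert np.isnan(p)
        assert n_used == 0

    def test_truncates_to_top_20(self, panel):
        al = _panel_aligned(panel, b_xy=0.2)
        assert len(al) == 30
        cfg = SMRConfig(heidi_r2_min=0.0, heidi_r2_max=1.01)
        _, _, n_used = heidi_components(al, int(panel.pos[15]), panel, cfg)
        assert n_used <= 19  # top 20 candidates including the top SNP

    def test_quadform_tail_matches_empirical_null(self, panel):
        """Analytic HEIDI p vs a 1e5-draw null of the same quadratic form."""
        spec = ScenarioSpec(kind="pleiotropy", m_snps=30, seed=3)
        gwas, probe = simulate_scenario(spec, panel)
        al = harmonize(gwas, probe, panel)
        cfg = SMRConfig(heidi_p_qtl=1.0, heidi_r2_min=0.0)  # all cis SNPs eligible
        T, eig, n_used = heidi_components(al, probe.probe_pos, panel, cfg)
        assert n_used >= 3
        rng = np.random.default_rng(0)
        draws = rng.chisquare(1, size=(100_000, eig.size)) @ eig
        emp = (draws >= T).mean()
        p = weighted_chisq_sf(T, eig)
        se = np.sqrt(max(emp * (1 - emp), 1e-12) / draws.shape[0])
        assert abs(p - emp) <= 3 * se + 1e-4


class TestSmrMulti:
    def test_single_instrument_reduces_to_single_snp(self, panel):
        inst = _panel_aligned(panel, b_xy=0.1, n_snps=1)
        p = smr_multi(inst, panel)
        top = inst.iloc[0]
        s = smr_single(top["b_gwas"], top["se_gwas"], top["b_qtl"], top["se_qtl"])
        assert p == pytest.approx(s.p_smr)

    def test_perfectly_correlated_pruned_to_one(self, panel):
        # duplicate the same SNP row: r^2 = 1 >= prune threshold
        inst = _panel_aligned(panel, b_xy=0.1, n_snps=1)
        doubled = pd.concat([inst, inst], ignore_index=True)
        p = smr_multi(doubled, panel)
        assert p == pytest.approx(smr_multi(inst, panel))

    def test_independent_pair_matches_mc(self, panel_indep):
        """Two near-independent strong instruments vs simulated null."""
        z_x = 30.0
        rows = []
        for i, zg in zip([0, 5], [1.7, -2.1]):
            rows.append(
                dict(
                    snp=panel_indep.snp_ids[i], chrom="1",
                    pos=int(panel_indep.pos[i]),
                    a1=panel_indep.effect_allele[i],
                    a2=panel_indep.other_allele[i],
                    freq=0.3, freq_gwas=0.3,
                    b_gwas=zg * 0.004, se_gwas=0.004, p_gwas=0.1, n_gwas=1000,
                    b_qtl=z_x * 0.01, se_qtl=0.01, p_qtl=1e-30,
                    palindromic=False,
                )
            )
        inst = _aligned(rows)
        p = smr_multi(inst, panel_indep)

        rng = np.random.default_rng(1)
        zg = rng.standard_normal((100_000, 2))
        zx = z_x + rng.standard_normal((100_000, 2))
        t = (zg**2 * zx**2) / (zg**2 + zx**2)
        T_obs = sum(
            smr_single(r["b_gwas"], r["se_gwas"], r["b_qtl"], r["se_qtl"]).t_smr
            for _, r in inst.iterrows()
        )
        emp = (t.sum(axis=1) >= T_obs).mean()
        se = np.sqrt(emp * (1 - emp) / 100_000)
        assert abs(p - emp) <= 3 * se + 1e-3


class TestSMRModel:
    def _probes(self, panel, n_good=7, n_bad=3):
        probes = []
        for k in range(n_good + n_bad):
            spec = ScenarioSpec(kind="pleiotropy", seed=100 + k)
            gwas, probe = simulate_scenario(spec, panel)
            probe.probe_id = f"probe{k + 1}"
            if k >= n_good:  # cripple the instrument
                probe.records["p"] = 0.5
            probes.append((gwas, probe))
        return probes

    def test_bookkeeping_and_skips(self, panel):
        pairs = self._probes(panel)
        gwas = pairs[0][0]
        res = SMRModel(gwas, [p for _, p in pairs], panel, disease="PD").fit()
        assert len(res.frame) == 7
        assert len(res.skipped) == 3
        assert all(reason == "no instrument" for _, reason in res.skipped)

    def test_deterministic_output(self, panel, tmp_path):
        spec = ScenarioSpec(kind="pleiotropy", seed=9)
        gwas, probe = simulate_scenario(spec, panel)
        out = []
        for tag in ("a", "b"):
            res = SMRModel(gwas, probe, panel, disease="PD").fit()
            path = tmp_path / f"{tag}.tsv"
            res.to_tsv(path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_recovers_simulated_effect(self, panel):
        spec = ScenarioSpec(kind="pleiotropy", b_xy=0.2, seed=21)
        gwas, probe = simulate_scenario(spec, panel)
        res = SMRModel(gwas, probe, panel, disease="PD").fit()
        row = res.frame.iloc[0]
        assert row["b_SMR"] == pytest.approx(0.2, abs=0.12)
        assert row["p_SMR_multi"] < 1e-4
        assert res.summary().startswith("SMR results")
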