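"""Summary-statistics I/O, harmonization and the Z-score completion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from smrtriage.sumstats import (
    QTLProbe,
    QTLSerializationError,
    SummaryStatRecord,
    SumstatsFormatError,
    harmonize,
    load_qtl,
    read_gwas_ma,
    serialize_qtl,
    write_gwas_ma,
    z_to_beta_se,
)


def _write(tmp_path, text, name="gwas.ma"):
    p = tmp_path / name
    p.write_text(text)
    return p


WELL_FORMED = """SNP A1 A2 freq b se p n
rs1 a g 0.30 0.10 0.02 1e-6 1000
rs2 C T 0.50 -0.05 0.01 1e-4 1000
rs3 G A 0.10 0.00 0.03 0.99 1000
"""


class TestReadGwasMa:
    def test_well_formed_parse_uppercases_alleles(self, tmp_path):
        df = read_gwas_ma(_write(tmp_path, WELL_FORMED))
        assert len(df) == 3
        assert df["a1"].tolist() == ["A", "C", "G"]
        assert df.attrs["rejected"] == []

    def test_invalid_rows_rejected_with_report(self, tmp_path):
        text = WELL_FORMED + "rs4 A C 0.2 0.1 0 0.5 1000\nrs5 A C 0.2 xx 0.1 0.5 1000\n"
        df = read_gwas_ma(_write(tmp_path, text))
        assert len(df) == 3
        reasons = {r["snp"]: r["reason"] for r in df.attrs["rejected"]}
        assert reasons == {"rs4": "se <= 0", "rs5": "non-numeric b/se/p"}
        assert {r["row"] for r in df.attrs["rejected"]} == {4, 5}

    def test_missing_column_names_the_column(self, tmp_path):
        text = "SNP A1 A2 freq b se p\nrs1 A G 0.3 0.1 0.02 1e-6\n"
        with pytest.raises(SumstatsFormatError, match="n"):
            read_gwas_ma(_write(tmp_path, text))

    def test_duplicate_snp_listed(self, tmp_path):
        text = WELL_FORMED + "rs1 A G 0.3 0.1 0.02 1e-6 1000\n"
        with pytest.raises(SumstatsFormatError, match="rs1"):
            read_gwas_ma(_write(tmp_path, text))

    def test_roundtrip_bit_identical(self, tmp_path, rng):
        n = 1000
        df = pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(n)],
                "a1": rng.choice(list("ACGT"), n),
                "a2": "X",
                "freq": rng.uniform(0.01, 0.99, n).round(6),
                "b": rng.normal(0, 0.1, n),
                "se": rng.uniform(0.01, 0.2, n),
                "p": rng.uniform(1e-12, 1, n),
                "n": 2119,
            }
        )
        df["a2"] = [c if c != a else ("A" if c != "A" else "G")
                    for a, c in zip(df["a1"], rng.choice(list("ACGT"), n))]
        p1 = tmp_path / "one.ma"
        p2 = tmp_path / "two.ma"
        write_gwas_ma(df, p1)
        write_gwas_ma(read_gwas_ma(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestRecordInvariants:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(a1="A", a2="A"), "identical alleles"),
            (dict(se=0.0), "se must be"),
            (dict(p=0.0), "outside"),
            (dict(freq_a1=1.2), "outside"),
        ],
    )
    def test_violations_raise(self, kwargs, msg):
        base = dict(snp_id="rs1", a1="A", a2="G", freq_a1=0.3, beta=0.1, se=0.02, p=0.5, n=100)
        base.update(kwargs)
        with pytest.raises(ValueError, match=msg):
            SummaryStatRecord(**base)


def _probe(records):
    return QTLProbe(
        probe_id="pr1", chrom="1", probe_pos=1_000_000,
        omic="eQTL", tissue="blood", gene_symbol="G1",
        records=pd.DataFrame(records),
    )


def _qtl_rec(snp, pos, a1="A", a2="G", freq=0.3, b=0.5, se=0.05, p=1e-20):
    return dict(snp=snp, chrom="1", pos=pos, a1=a1, a2=a2, freq=freq, b=b, se=se, p=p)


def _gwas_row(snp, a1="A", a2="G", freq=0.3, b=0.1, se=0.02, p=1e-6, n=1000):
    return dict(snp=snp, a1=a1, a2=a2, freq=freq, b=b, se=se, p=p, n=n)


class TestHarmonize:
    def test_identical_alleles_pass_through(self):
        gwas = pd.DataFrame([_gwas_row("rs1")])
        out = harmonize(gwas, _probe([_qtl_rec("rs1", 999_000)]))
        assert out.loc[0, "b_gwas"] == pytest.approx(0.1)
        assert out.loc[0, "freq_gwas"] == pytest.approx(0.3)

    def test_swapped_alleles_flip_beta_and_freq(self):
        gwas = pd.DataFrame([_gwas_row("rs1", a1="G", a2="A", b=0.3, freq=0.7)])
        out = harmonize(gwas, _probe([_qtl_rec("rs1", 999_000)]))
        assert out.loc[0, "b_gwas"] == pytest.approx(-0.3)
        assert out.loc[0, "freq_gwas"] == pytest.approx(0.3)

    def test_allele_set_mismatch_dropped(self):
        gwas = pd.DataFrame([_gwas_row("rs1", a1="A", a2="C"), _gwas_row("rs2")])
        probe = _probe([_qtl_rec("rs1", 999_000), _qtl_rec("rs2", 999_500)])
        out = harmonize(gwas, probe)
        assert out["snp"].tolist() == ["rs2"]
        assert out.attrs["dropped"]["allele_mismatch"] == ["rs1"]

    def test_freq_mismatch_dropped_and_logged(self):
        gwas = pd.DataFrame([_gwas_row("rs1", freq=0.65)])
        out = harmonize(gwas, _probe([_qtl_rec("rs1", 999_000, freq=0.3)]), freq_tol=0.2)
        assert out.empty
        assert out.attrs["dropped"]["freq_mismatch"] == ["rs1"]

    def test_no_shared_variants_raises(self):
        gwas = pd.DataFrame([_gwas_row("rsX")])
        with pytest.raises(ValueError, match="no shared variants"):
            harmonize(gwas, _probe([_qtl_rec("rs1", 999_000)]))

    def test_palindromic_flagged_not_dropped(self):
        gwas = pd.DataFrame([_gwas_row("rs1", a1="A", a2="T")])
        out = harmonize(gwas, _probe([_qtl_rec("rs1", 999_000, a1="A", a2="T")]))
        assert out.loc[0, "palindromic"]

    def test_swap_involution_restores_original(self):
        # relabelling the effect allele (a1<->a2, b -> -b, f -> 1-f) encodes
        # the same association; harmonization must restore it exactly
        probe = _probe([_qtl_rec("rs1", 999_000)])
        orig = pd.DataFrame([_gwas_row("rs1", b=0.17, freq=0.41)])
        relabeled = orig.assign(a1="G", a2="A", b=-0.17, freq=1 - 0.41)
        a = harmonize(orig, probe)
        b = harmonize(relabeled, probe)
        assert b.loc[0, "b_gwas"] == pytest.approx(a.loc[0, "b_gwas"])
        assert b.loc[0, "freq_gwas"] == pytest.approx(a.loc[0, "freq_gwas"])


class TestZToBetaSe:
    def test_zero_z(self):
        beta, se = z_to_beta_se(0.0, 0.3, 2119)
        assert beta == 0.0
        assert se == pytest.approx(1 / np.sqrt(2 * 0.3 * 0.7 * 2119))

    def test_closed_form(self):
        z, f, n = 2.4, 0.1, 2119
        beta, se = z_to_beta_se(z, f, n)
        expect_se = 1 / np.sqrt(2 * f * (1 - f) * (n + z * z))
        assert se == pytest.approx(expect_se, rel=1e-12)
        assert beta == pytest.approx(z * expect_se, rel=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        z=st.floats(-50, 50),
        f=st.floats(0.001, 0.999),
        n=st.integers(2, 10_000_000),
    )
    def test_ratio_identity_and_monotonicity(self, z, f, n):
        beta, se = z_to_beta_se(z, f, n)
        if z != 0:
            assert beta / se == pytest.approx(z, rel=1e-9)
        _, se_bigger_n = z_to_beta_se(z, f, 2 * n)
        assert se_bigger_n < se

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            z_to_beta_se(1.0, 0.0, 100)


class TestReadQtlLong:
    def test_groups_rows_into_probes(self, tmp_path):
        from smrtriage.sumstats import read_qtl_long

        path = tmp_path / "qtl.tsv"
        header = "probe\tgene\tomic\ttissue\tancestry\tsnp\tchrom\tpos\ta1\ta2\tfreq\tb\tse\tp\n"
        rows = [
            "p1\tG1\teQTL\tblood\tEUR\trs1\t1\t1000\ta\tg\t0.3\t0.5\t0.05\t1e-20",
            "p1\tG1\teQTL\tblood\tEUR\trs2\t1\t2000\tC\tT\t0.4\t0.2\t0.05\t1e-4",
            "p2\tG2\tmQTL\tbrain\tmulti\trs3\t2\t500\tA\tG\t0.2\t-0.1\t0.02\t0.01",
        ]
        path.write_text(header + "\n".join(rows) + "\n")
        probes = read_qtl_long(path)
        assert [p.probe_id for p in probes] == ["p1", "p2"]
        assert probes[0].records["a1"].tolist() == ["A", "C"]
        assert probes[1].omic == "mQTL" and probes[1].ancestry == "multi"


class TestQtlStore:
    def _dataset(self):
        p1 = _probe([_qtl_rec("rs1", 999_000), _qtl_rec("rs2", 999_500, a1="C", a2="T")])
        p2 = QTLProbe(
            probe_id="pr2", chrom="1", probe_pos=1_500_000,
            omic="mQTL", tissue="brain", gene_symbol=None, ancestry="multi",
            records=pd.DataFrame(
                [_qtl_rec("rs2", 999_500, a1="C", a2="T"),
                 _qtl_rec("rs3", 1_400_000), _qtl_rec("rs4", 1_600_000),
                 _qtl_rec("rs5", 1_700_000)]
            ),
        )
        return [p1, p2]

    def test_roundtrip(self, tmp_path):
        probes = self._dataset()
        serialize_qtl(probes, tmp_path / "qtl")
        back = load_qtl(tmp_path / "qtl")
        assert [p.probe_id for p in back] == ["pr1", "pr2"]
        for a, b in zip(probes, back):
            assert a.omic == b.omic and a.tissue == b.tissue
            assert a.gene_symbol == b.gene_symbol and a.ancestry == b.ancestry
            pd.testing.assert_frame_equal(
                a.records, b.records, check_dtype=False, check_like=True
            )

    def test_empty_dataset(self, tmp_path):
        serialize_qtl([], tmp_path / "qtl")
        assert load_qtl(tmp_path / "qtl") == []

    def test_missing_beta_roundtrips_as_missing(self, tmp_path):
        rec = _qtl_rec("rs1", 999_000)
        rec["b"] = np.nan
        serialize_qtl([_probe([rec])], tmp_path / "qtl")
        back = load_qtl(tmp_path / "qtl")
        assert np.isnan(back[0].records.loc[0, "b"])

    def test_unknown_variant_in_index_errors(self, tmp_path):
        vidx = pd.DataFrame(
            [{"snp": "rsZ", "chrom": "1", "pos": 1, "a1": "A", "a2": "G", "freq": 0.5}]
        )
        with pytest.raises(QTLSerializationError, match="absent"):
            serialize_qtl([_probe([_qtl_rec("rs1", 999_000)])], tmp_path / "q", vidx)

    @settings(
        max_examples=20,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(seed=st.integers(0, 10_000))
    def test_random_roundtrip_lossless(self, seed, tmp_path):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 8))
        recs = [
            _qtl_rec(f"rs{i}", 990_000 + 1000 * i,
                     freq=float(rng.uniform(0.05, 0.95)),
                     b=float(rng.normal()), se=float(rng.uniform(0.01, 1)),
                     p=float(rng.uniform(1e-30, 1)))
            for i in range(n)
        ]
        prefix = tmp_path / f"q{seed}"
        serialize_qtl([_probe(recs)], prefix)
        back = load_qtl(prefix)
        pd.testing.assert_frame_equal(
            _probe(recs).records, back[0].records, check_dtype=False
        )
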