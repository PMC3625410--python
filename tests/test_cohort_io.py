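"""Variable coding, table ingest, exposure transforms and genetic QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxescreen.cohort_io import (
    CohortSchema,
    ExposurePanel,
    RiskAlleleMap,
    allele_frequency,
    code_genotypes_from_vcf,
    define_cases,
    hwe_test,
    read_cohort,
    transform_exposures,
)
from gxescreen.synthetic_cohort import generate_cohort, study_spec

# --------------------------------------------------------------------- VCF

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def _write_vcf(path, records):
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in records))


@pytest.fixture()
def vcf_path(tmp_path):
    records = [
        # risk allele A is ALT here
        "1\t100\trsALT\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0",
        # risk allele G is REF: dosage must follow the map, not orientation
        "1\t200\trsREF\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
        # missing call
        "1\t300\trsMISS\tC\tT\t.\tPASS\t.\tGT\t./.\t0/1\t1/1",
        # mapped allele not among REF/ALT
        "1\t400\trsBAD\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
    ]
    p = tmp_path / "geno.vcf"
    _write_vcf(p, records)
    return p


class TestVcfCoding:
    def test_risk_allele_is_alt(self, vcf_path):
        rmap = RiskAlleleMap({"rsALT": ("A", "")})
        d = code_genotypes_from_vcf(vcf_path, rmap)
        assert d["rsALT"].tolist() == [1.0, 2.0, 0.0]

    def test_risk_allele_is_ref_orientation_respected(self, vcf_path):
        rmap = RiskAlleleMap({"rsREF": ("G", "")})
        d = code_genotypes_from_vcf(vcf_path, rmap)
        # G/G carries two copies of the risk (REF) allele
        assert d["rsREF"].tolist() == [2.0, 1.0, 0.0]

    def test_missing_call_gives_missing_dosage(self, vcf_path):
        rmap = RiskAlleleMap({"rsMISS": ("T", "")})
        d = code_genotypes_from_vcf(vcf_path, rmap)
        assert np.isnan(d["rsMISS"].iloc[0])
        assert d["rsMISS"].iloc[1:].tolist() == [1.0, 2.0]

    def test_allele_mismatch_fatal(self, vcf_path):
        rmap = RiskAlleleMap({"rsBAD": ("G", "")})
        with pytest.raises(ValueError, match="neither REF"):
            code_genotypes_from_vcf(vcf_path, rmap)

    def test_absent_site_all_missing(self, vcf_path):
        rmap = RiskAlleleMap({"rsNOPE": ("A", "")})
        d = code_genotypes_from_vcf(vcf_path, rmap)
        assert d["rsNOPE"].isna().all()

    def test_round_trip_from_known_dosages(self, tmp_path):
        # dosages -> VCF genotypes -> coded dosages must be the identity
        rng = np.random.default_rng(5)
        dosages = rng.integers(0, 3, size=20)
        gt = {0: "0/0", 1: "0/1", 2: "1/1"}  # ALT is the risk allele
        samples = "\t".join(f"S{i}" for i in range(20))
        header = VCF_HEADER.replace("S1\tS2\tS3", samples)
        rec = "1\t500\trsRT\tC\tT\t.\tPASS\t.\tGT\t" + "\t".join(
            gt[int(d)] for d in dosages
        )
        p = tmp_path / "rt.vcf"
        p.write_text(header + rec + "\n")
        d = code_genotypes_from_vcf(p, RiskAlleleMap({"rsRT": ("T", "")}))
        np.testing.assert_array_equal(d["rsRT"].to_numpy(), dosages.astype(float))

    def test_site_matched_by_chrom_pos_fallback(self, tmp_path):
        records = ["1\t700\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0"]
        p = tmp_path / "nopid.vcf"
        _write_vcf(p, records)
        d = code_genotypes_from_vcf(p, RiskAlleleMap({"1:700": ("A", "")}))
        assert d["1:700"].tolist() == [1.0, 2.0, 0.0]

    def test_risk_map_rejects_bad_base(self):
        with pytest.raises(ValueError):
            RiskAlleleMap({"rs1": ("N", "")})


# ----------------------------------------------------------------- tables


def _cohort_text(rows):
    head = "pid\toutcome\tage\tsex\trace\tbmi\tstratum\tpsu\tweight\texpo\tsnp1"
    return head + "\n" + "\n".join(rows) + "\n"


@pytest.fixture()
def schema():
    return CohortSchema(
        participant_id="pid", exposures=["expo"], snps=["snp1"]
    )


class TestReadCohort:
    def test_reads_complete_fixture(self, tmp_path, schema):
        p = tmp_path / "c.tsv"
        rows = [
            f"P{i}\t{i % 2}\t50\tfemale\tw\t25\t1\t1\t1.5\t3.2\t1" for i in range(5)
        ]
        p.write_text(_cohort_text(rows))
        tab = read_cohort(p, schema)
        assert len(tab) == 5
        assert tab["outcome"].tolist() == [0, 1, 0, 1, 0]

    def test_zero_weight_fatal_and_names_row(self, tmp_path, schema):
        p = tmp_path / "c.tsv"
        rows = [
            "P0\t0\t50\tfemale\tw\t25\t1\t1\t1.5\t3.2\t1",
            "P1\t1\t50\tmale\tw\t25\t1\t1\t0\t3.2\t1",
        ]
        p.write_text(_cohort_text(rows))
        with pytest.raises(ValueError, match="P1"):
            read_cohort(p, schema)

    def test_duplicate_ids_fatal(self, tmp_path, schema):
        p = tmp_path / "c.tsv"
        rows = ["P0\t0\t50\tfemale\tw\t25\t1\t1\t1\t3.2\t1"] * 2
        p.write_text(_cohort_text(rows))
        with pytest.raises(ValueError, match="duplicated"):
            read_cohort(p, schema)

    def test_fbg_without_outcome_loads(self, tmp_path):
        schema = CohortSchema(participant_id="pid", outcome=None, fbg="fbg")
        p = tmp_path / "c.tsv"
        p.write_text(
            "pid\tfbg\tstratum\tpsu\tweight\nP0\t130\t1\t1\t1\nP1\t110\t1\t2\t1\n"
        )
        tab = read_cohort(p, schema)
        assert "outcome" not in tab.columns
        assert define_cases(tab["fbg"]).tolist() == [1.0, 0.0]

    def test_missing_design_column_fatal(self, tmp_path, schema):
        p = tmp_path / "c.tsv"
        p.write_text("pid\toutcome\nP0\t1\n")
        with pytest.raises(ValueError, match="absent"):
            read_cohort(p, schema)


class TestDefineCases:
    def test_threshold_boundary_is_a_case(self):
        # the clinical cutoff is inclusive: FBG of exactly 126 mg/dL is a case
        assert define_cases(pd.Series([126.0])).iloc[0] == 1.0

    def test_below_threshold_is_control(self):
        assert define_cases(pd.Series([125.9])).iloc[0] == 0.0

    def test_missing_propagates(self):
        assert np.isnan(define_cases(pd.Series([np.nan])).iloc[0])

    def test_negative_fbg_fatal(self):
        with pytest.raises(ValueError):
            define_cases(pd.Series([-1.0]))


class TestTransformExposures:
    def test_log10_standardization_hand_oracle(self):
        # {10, 100, 1000} -> log10 {1,2,3} -> z-scores {-1, 0, 1}
        df = pd.DataFrame({"x": [10.0, 100.0, 1000.0]})
        panel = ExposurePanel(columns=["x"])
        out = transform_exposures(df, panel)
        np.testing.assert_allclose(out["x"], [-1.0, 0.0, 1.0], atol=1e-12)
        assert panel.moments["x"] == (2.0, 1.0)

    def test_raw_mode_differs_from_log(self):
        df = pd.DataFrame({"x": [10.0, 100.0, 1000.0]})
        out_raw = transform_exposures(df, ExposurePanel(columns=["x"], transform="raw"))
        assert not np.allclose(out_raw["x"], [-1.0, 0.0, 1.0])

    def test_restandardizing_standardized_column_is_identity(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.lognormal(1, 0.4, 500)})
        once = transform_exposures(df, ExposurePanel(columns=["x"]))
        # a standardized column has mean 0 / sd 1, so an identity-transform
        # restandardization must return it unchanged
        z = once["x"]
        again = transform_exposures(once, ExposurePanel(columns=["x"], transform="raw"))
        np.testing.assert_allclose(again["x"], z, atol=1e-12)

    def test_constant_column_fatal(self):
        with pytest.raises(ValueError, match="variance"):
            transform_exposures(
                pd.DataFrame({"x": [5.0] * 4}), ExposurePanel(columns=["x"])
            )

    def test_nonpositive_under_log_fatal(self):
        with pytest.raises(ValueError, match="non-positive"):
            transform_exposures(
                pd.DataFrame({"x": [1.0, 0.0, 2.0]}), ExposurePanel(columns=["x"])
            )

    def test_weighted_moments_option(self):
        df = pd.DataFrame({"x": [10.0, 100.0]})
        panel = ExposurePanel(columns=["x"], transform="log10", weighted_moments=True)
        transform_exposures(df, panel, weights=np.array([3.0, 1.0]))
        mean, _ = panel.moments["x"]
        assert mean == pytest.approx(1.25)  # weighted mean of log10 {1, 2}


class TestAlleleFrequency:
    def test_all_homozygous_risk(self):
        assert allele_frequency(pd.Series([2, 2, 2]))["all"] == 1.0

    def test_half_frequency(self):
        assert allele_frequency(pd.Series([0, 1, 2]))["all"] == 0.5

    def test_empty_group_missing(self):
        f = allele_frequency(pd.Series([1.0, np.nan]), pd.Series(["a", "b"]))
        assert f["a"] == 0.5 and np.isnan(f["b"])

    def test_recovers_high_generating_frequency(self):
        # one locus is generated at 97% risk-allele frequency in one group
        spec = study_spec(n_participants=20_000, seed=9, with_missingness=False)
        cohort = generate_cohort(spec).cohort
        f = allele_frequency(cohort["snp06"], cohort["race"])
        assert f["nh_black"] == pytest.approx(0.97, abs=0.01)


class TestHwe:
    @pytest.mark.parametrize("counts", [(25, 50, 25), (36, 48, 16)])
    def test_exact_proportions_give_null(self, counts):
        chi2, p = hwe_test(*counts)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_independent_pearson_oracle(self):
        n0, n1, n2 = 50, 20, 30
        n = n0 + n1 + n2
        q = (n1 + 2 * n2) / (2 * n)
        expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        oracle = stats.chisquare([n0, n1, n2], expected, ddof=1)
        chi2, p = hwe_test(n0, n1, n2)
        assert chi2 == pytest.approx(oracle.statistic)
        assert p == pytest.approx(oracle.pvalue)

    def test_invariant_to_allele_swap(self):
        assert hwe_test(50, 20, 30)[0] == pytest.approx(hwe_test(30, 20, 50)[0])

    def test_monomorphic_convention(self):
        assert hwe_test(10, 0, 0) == (0.0, 1.0)

    def test_exact_test_matches_enumeration_oracle(self):
        # brute-force conditional distribution of the heterozygote count
        from fractions import Fraction
        from math import factorial

        n0, n1, n2 = 12, 6, 2
        n = n0 + n1 + n2
        rare = min(n1 + 2 * n0, n1 + 2 * n2)

        def prob(h):
            hom_r = (rare - h) // 2
            hom_c = n - h - hom_r
            return Fraction(
                factorial(n) * 2**h * factorial(rare) * factorial(2 * n - rare),
                factorial(hom_r) * factorial(hom_c) * factorial(h) * factorial(2 * n),
            )

        dist = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
        expected = float(sum(p for p in dist.values() if p <= dist[n1]))
        _, p = hwe_test(n0, n1, n2, method="exact")
        assert p == pytest.approx(expected, rel=1e-10)

    def test_exact_test_agrees_with_chisq_at_large_counts(self):
        _, p_exact = hwe_test(500, 480, 120, method="exact")
        _, p_chi = hwe_test(500, 480, 120)
        assert p_exact == pytest.approx(p_chi, abs=0.05)

    def test_empty_sample_fatal(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)
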