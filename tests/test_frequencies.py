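"""Frequency table IO, EAS/SAS pooling, carrier-frequency summation, exact CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from genoprev import (
    ASIAN,
    GroupCarrierFrequency,
    adjust_for_unknown,
    clopper_pearson,
    pool_asian,
    sum_carrier_frequency,
)
from genoprev.frequencies import load_frequency_table

from conftest import gaf


class TestLoadFrequencyTable:
    def test_row_parses_to_record(self, tmp_path):
        p = tmp_path / "f.tsv"
        # af printed at 6 decimals; the exact ratio 12/35354 is stored
        p.write_text("rsid\tgroup\tac\tan\taf\nrs104893944\tAMR\t12\t35354\t0.000339\n")
        (rec,) = load_frequency_table(p)
        assert rec.allele_count == 12
        assert rec.frequency == pytest.approx(0.000339, abs=5e-7)
        assert rec.frequency == 12 / 35354

    def test_inconsistent_af_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("rsid\tgroup\tac\tan\taf\nrs1\tNFE\t12\t35354\t0.000500\n")
        with pytest.raises(ValueError, match="inconsistent"):
            load_frequency_table(p)

    def test_k_greater_than_n_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("rsid\tgroup\tac\tan\taf\nrs1\tNFE\t10\t5\t2.0\n")
        with pytest.raises(ValueError, match="row 2"):
            load_frequency_table(p)

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("rsid\tgroup\tac\tan\taf\n")
        assert load_frequency_table(p) == []

    def test_fin_rows_skipped_with_warning(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            "rsid\tgroup\tac\tan\taf\nrs1\tFIN\t0\t100\t0.0\nrs1\tNFE\t1\t100\t0.01\n"
        )
        with pytest.warns(UserWarning, match="FIN"):
            recs = load_frequency_table(p)
        assert [r.group for r in recs] == ["NFE"]

    def test_unknown_group_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("rsid\tgroup\tac\tan\taf\nrs1\tXYZ\t1\t100\t0.01\n")
        with pytest.raises(ValueError, match="XYZ"):
            load_frequency_table(p)


class TestPoolAsian:
    def test_counts_add(self):
        recs = [gaf("rs1", "EAS", 2, 20000), gaf("rs1", "SAS", 3, 30000)]
        (pooled,) = pool_asian(recs)
        assert pooled.group == ASIAN
        assert (pooled.allele_count, pooled.allele_number) == (5, 50000)
        assert pooled.frequency == pytest.approx(1e-4)

    def test_single_source_carries_through(self):
        (pooled,) = pool_asian([gaf("rs1", "EAS", 0, 100)])
        assert (pooled.group, pooled.allele_count, pooled.allele_number) == (ASIAN, 0, 100)

    def test_no_asian_records_no_asian_output(self):
        recs = [gaf("rs1", "NFE", 1, 100)]
        assert pool_asian(recs) == recs

    def test_duplicate_group_per_variant_rejected(self):
        recs = [gaf("rs1", "EAS", 1, 100), gaf("rs1", "EAS", 2, 100)]
        with pytest.raises(ValueError, match="duplicate"):
            pool_asian(recs)

    def test_pool_then_sum_equals_sum_then_pool(self):
        # disjoint variant sets: order of pooling vs summation is irrelevant
        recs = [
            gaf("rs1", "EAS", 2, 10000),
            gaf("rs1", "SAS", 1, 20000),
            gaf("rs2", "EAS", 3, 10000),
            gaf("rs2", "SAS", 2, 20000),
        ]
        summed_after = sum_carrier_frequency(pool_asian(recs), ASIAN, {"rs1", "rs2"})
        per_variant = [sum_carrier_frequency(pool_asian(recs), ASIAN, {v}) for v in ("rs1", "rs2")]
        assert summed_after.f == pytest.approx(sum(p.f for p in per_variant))


class TestSumCarrierFrequency:
    def test_reference_totals(self, frequency_fixture):
        pooled = pool_asian(frequency_fixture)
        ids = {r.variant_id for r in pooled}
        assert sum_carrier_frequency(pooled, "NFE", ids).f == pytest.approx(0.000865)
        assert sum_carrier_frequency(pooled, "AMR", ids).f == pytest.approx(0.001404)
        assert sum_carrier_frequency(pooled, "AFR", ids).f == pytest.approx(0.000186)
        assert sum_carrier_frequency(pooled, ASIAN, ids).f == pytest.approx(0.001228)

    def test_singleton_sum_is_that_frequency(self):
        recs = [gaf("rs1", "NFE", 5, 1000), gaf("rs2", "NFE", 3, 1000)]
        assert sum_carrier_frequency(recs, "NFE", {"rs1"}).f == pytest.approx(0.005)

    def test_absent_group_flagged_not_silent(self):
        out = sum_carrier_frequency([gaf("rs1", "NFE", 1, 100)], "AFR", {"rs1"})
        assert out.missing
        assert out.f == 0.0

    def test_empty_pathogenic_set_is_error(self):
        with pytest.raises(ValueError):
            sum_carrier_frequency([], "NFE", set())

    def test_ci_brackets_point_estimate(self, frequency_fixture):
        pooled = pool_asian(frequency_fixture)
        ids = {r.variant_id for r in pooled}
        for g in ("NFE", "AFR", "AMR", ASIAN):
            gcf = sum_carrier_frequency(pooled, g, ids)
            assert gcf.ci_low <= gcf.f <= gcf.ci_high


class TestAdjustForUnknown:
    def test_direct_division(self):
        gcf = GroupCarrierFrequency("NFE", 0.000583, 583, 10**6, 0.0005, 0.0007)
        out = adjust_for_unknown(gcf, 0.583)
        assert out.f == pytest.approx(0.001, rel=1e-3)
        assert out.coverage_adjusted

    def test_identity_at_full_coverage(self):
        gcf = GroupCarrierFrequency("NFE", 0.001, 100, 10**5, 0.0008, 0.0012)
        assert adjust_for_unknown(gcf, 1.0).f == gcf.f

    def test_zero_frequency_stays_zero(self):
        gcf = GroupCarrierFrequency("NFE", 0.0, 0, 10**5, 0.0, 0.0001)
        assert adjust_for_unknown(gcf, 0.5).f == 0.0

    def test_zero_coverage_rejected(self):
        gcf = GroupCarrierFrequency("NFE", 0.001, 100, 10**5, 0.0008, 0.0012)
        with pytest.raises(ValueError):
            adjust_for_unknown(gcf, 0.0)

    @given(
        f=st.floats(min_value=0, max_value=0.01),
        cov=st.floats(min_value=0.1, max_value=1.0),
        scale=st.floats(min_value=0.1, max_value=5.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_linear_in_f_inverse_in_coverage(self, f, cov, scale):
        def adj(x, c):
            gcf = GroupCarrierFrequency("NFE", x, 0, 0, 0.0, 0.0)
            return adjust_for_unknown(gcf, c).f

        assert adj(scale * f, cov) == pytest.approx(scale * adj(f, cov), rel=1e-9)
        assert adj(f, cov) * cov == pytest.approx(f, rel=1e-9)


class TestClopperPearson:
    def test_boundaries(self):
        lo, hi = clopper_pearson(0, 50)
        assert lo == 0.0 and hi < 1
        lo, hi = clopper_pearson(50, 50)
        assert hi == 1.0 and lo > 0

    @pytest.mark.parametrize(
        "k,n", [(5, 100), (0, 10), (10, 10), (1, 1000), (250, 500), (865, 10**6)]
    )
    def test_matches_independent_beta_inverse(self, k, n):
        """Cross-check against statsmodels' independent beta implementation."""
        lo, hi = clopper_pearson(k, n, alpha=0.05)
        ref_lo, ref_hi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(0.0 if np.isnan(ref_lo) else ref_lo, abs=1e-6)
        assert hi == pytest.approx(1.0 if np.isnan(ref_hi) else ref_hi, abs=1e-6)

    def test_brackets_point_estimate(self):
        for k, n in [(0, 7), (3, 7), (7, 7), (13, 990)]:
            lo, hi = clopper_pearson(k, n)
            assert lo <= k / n <= hi

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 0)
        with pytest.raises(ValueError):
            clopper_pearson(6, 5)
        with pytest.raises(ValueError):
            clopper_pearson(1, 5, alpha=1.5)

    def test_empirical_coverage_is_conservative(self, rng):
        """>=95% of exact intervals from 2000 binomial draws contain the truth."""
        n, q, reps = 5000, 0.001, 2000
        ks = rng.binomial(n, q, size=reps)
        covered = 0
        for k in ks:
            lo, hi = clopper_pearson(int(k), n)
            covered += lo <= q <= hi
        assert covered / reps >= 0.95
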