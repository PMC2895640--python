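"""Plating-assay statistics: frequencies, fluctuation rates, t tests and
dose-modifying factors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dsbrec import karyosim, recomb_stats
from dsbrec.recomb_stats import (FluctuationAssay, FrequencyRecord,
                                 SurvivalCurve, dose_modifying_factor,
                                 frequency, induction_efficiency,
                                 lea_coulson_m, median_rate, net_frequency,
                                 summary_t_test)


def _record(sel, sel_cells, tot, tot_cells, **kw):
    return FrequencyRecord(strain="s", selective_colonies=sel,
                           selective_cells_plated=sel_cells,
                           total_colonies=tot, total_cells_plated=tot_cells, **kw)


class TestFrequency:
    def test_per_survivor_arithmetic(self):
        est = frequency(_record(20, 1e7, 100, 100))  # full survival
        assert est.value == pytest.approx(2e-6)

    def test_survivor_correction_doubles_frequency_at_half_survival(self):
        est = frequency(_record(20, 1e7, 50, 100))
        assert est.value == pytest.approx(4e-6)

    def test_zero_selective_colonies_reports_resolution_bound(self):
        est = frequency(_record(0, 1e7, 100, 100))
        assert est.value == 0.0
        assert est.resolution_bound == pytest.approx(1e-7)

    def test_zero_total_colonies_rejected(self):
        with pytest.raises(ValueError):
            frequency(_record(5, 1e7, 0, 100))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(k=st.floats(1.01, 1000))
    def test_dilution_bookkeeping_invariance(self, k):
        """Plating k-fold more cells and counting k-fold more colonies leaves
        the frequency unchanged."""
        base = frequency(_record(20, 1e6, 80, 100)).value
        scaled = frequency(_record(20 * k, 1e6 * k, 80, 100)).value
        assert scaled == pytest.approx(base)


class TestNetFrequency:
    @pytest.mark.parametrize("treated,untreated,value,neg", [
        (12e-6, 2e-6, 10e-6, False),
        (2e-6, 2e-6, 0.0, False),
        (1e-6, 2e-6, -1e-6, True),
    ])
    def test_subtraction_and_sign_flag(self, treated, untreated, value, neg):
        net = net_frequency(treated, untreated)
        assert net.value == pytest.approx(value)
        assert net.negative is neg


class TestInductionEfficiency:
    def test_exact_line(self):
        assert induction_efficiency([(10, 50e-6), (20, 100e-6)]) == \
            pytest.approx(5e-6)

    def test_no_induction(self):
        assert induction_efficiency([(10, 0.0), (20, 0.0)]) == 0.0

    def test_recovery_from_noisy_dose_series(self):
        rng = np.random.default_rng(0)
        doses = np.array([5.0, 10.0, 20.0, 40.0])
        net = 7e-6 * doses * rng.lognormal(0, 0.2, size=4)
        assert induction_efficiency(zip(doses, net)) == \
            pytest.approx(7e-6, rel=0.20)


class TestMedianRate:
    def test_median_equation_root_matches_bisection_oracle(self):
        # independent oracle: plain bisection on r0/m - ln m = 1.24
        def oracle(r0, lo=1e-9, hi=1e6):
            for _ in range(200):
                mid = (lo + hi) / 2
                if r0 / mid - math.log(mid) - 1.24 > 0:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        for r0 in (0.5, 1, 5, 33, 200):
            assert lea_coulson_m(r0) == pytest.approx(oracle(r0), rel=1e-6)

    def test_median_five_gives_m_near_2_37(self):
        assay = FluctuationAssay(counts=[5] * 11, cells_per_culture=1e7)
        est = median_rate(assay, n_boot=100, seed=0)
        assert est.m == pytest.approx(2.375, abs=0.01)
        assert est.rate == pytest.approx(2.375e-7, rel=1e-3)

    def test_rate_halves_when_cells_double(self):
        counts = [3, 8, 5, 0, 12, 6, 7]
        r1 = median_rate(FluctuationAssay(counts=counts, cells_per_culture=1e7),
                         n_boot=100, seed=0).rate
        r2 = median_rate(FluctuationAssay(counts=counts, cells_per_culture=2e7),
                         n_boot=100, seed=0).rate
        assert r1 == pytest.approx(2 * r2)

    def test_zero_median_reports_upper_bound_only(self):
        assay = FluctuationAssay(counts=[0, 0, 0, 1, 0, 2, 0],
                                 cells_per_culture=1e7)
        est = median_rate(assay, seed=0)
        assert est.below_resolution
        assert est.rate == 0.0
        assert est.ci_high > 0

    def test_too_few_cultures_rejected(self):
        with pytest.raises(ValueError):
            median_rate(FluctuationAssay(counts=[1, 2, 3],
                                         cells_per_culture=1e7))

    def test_ci_covers_generating_rate_in_most_replicate_assays(self):
        rate = 1.5e-6
        covered = 0
        n_assays = 100
        for i in range(n_assays):
            assay = karyosim.simulate_fluctuation(rate, 1e7, 24, seed=5000 + i)
            est = median_rate(assay, n_boot=2000, seed=i)
            covered += est.ci_low <= rate <= est.ci_high
        assert covered / n_assays >= 0.90


class TestSummaryTTest:
    def test_reproduces_published_comparison(self):
        # mean±SEM 18±3 vs 60±10 with n=6 per group
        res = summary_t_test(18, 3, 6, 60, 10, 6)
        assert abs(res.t) == pytest.approx(4.02, abs=0.01)
        assert res.df == 10
        assert res.p == pytest.approx(0.002, abs=5e-4)

    def test_identical_groups(self):
        res = summary_t_test(10, 2, 6, 10, 2, 6)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_welch_variant_is_more_conservative_here(self):
        pooled = summary_t_test(18, 3, 6, 60, 10, 6)
        welch = summary_t_test(18, 3, 6, 60, 10, 6, welch=True)
        assert welch.p > pooled.p
        assert welch.df == pytest.approx(5.89, abs=0.05)

    def test_one_tailed_halves_the_p(self):
        two = summary_t_test(18, 3, 6, 60, 10, 6, tails=2)
        one = summary_t_test(18, 3, 6, 60, 10, 6, tails=1)
        assert one.p == pytest.approx(two.p / 2)

    def test_matches_raw_data_pooled_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(5, 2, 8), rng.normal(7, 3, 12)
        res = summary_t_test(a.mean(), a.std(ddof=1) / math.sqrt(8), 8,
                             b.mean(), b.std(ddof=1) / math.sqrt(12), 12)
        ref = stats.ttest_ind(a, b)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestDoseModifyingFactor:
    def _curve(self, d0):
        return karyosim.simulate_survival(d0, [0, 10, 20, 40, 60, 80])

    def test_identical_curves_give_unity(self):
        c = self._curve(40)
        for level in (0.9, 0.5, 0.2):
            assert dose_modifying_factor(c, c, level) == pytest.approx(1.0)

    def test_exponentials_with_halved_d0(self):
        assert dose_modifying_factor(self._curve(40), self._curve(20), 0.4) == \
            pytest.approx(2.0)

    def test_reciprocity(self):
        a, b = self._curve(40), self._curve(25)
        assert dose_modifying_factor(a, b, 0.3) * \
            dose_modifying_factor(b, a, 0.3) == pytest.approx(1.0)

    def test_level_outside_curve_rejected(self):
        with pytest.raises(ValueError):
            dose_modifying_factor(self._curve(40), self._curve(20), 1e-6)


class TestSurvivalFromCounts:
    def test_dilution_corrected_ratio(self):
        import pandas as pd

        df = pd.DataFrame({
            "dose": [0, 0, 20, 20], "replicate": [1, 2, 1, 2],
            "cells_plated": [400, 400, 800, 800], "dilution": [1, 1, 1, 1],
            "colonies": [380, 420, 350, 370],
        })
        curve = recomb_stats.survival_from_counts(df)
        assert curve.surviving_fraction[0] == pytest.approx(1.0)
        assert curve.surviving_fraction[1] == pytest.approx(0.45, abs=0.01)

    def test_missing_dose_zero_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"dose": [20, 40], "cells_plated": [100, 100],
                           "dilution": [1, 1], "colonies": [50, 20]})
        with pytest.raises(ValueError):
            recomb_stats.survival_from_counts(df)
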