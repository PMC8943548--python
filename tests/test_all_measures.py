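"""Unit tests for the six all-data cleaning rules."""

import numpy as np
import pandas as pd
import pytest

from weightclean import AllDataConfig
from weightclean.allmeasures import (
    clean_breland,
    clean_buta,
    clean_chan_raffa,
    clean_littman,
    clean_maciejewski,
    clean_maguen,
    fit_longitudinal_trend,
    range_filter,
)

from conftest import build_cohort


def retained_weights(result):
    return sorted(result.retained["weight_kg"].tolist())


def reasons(result):
    return sorted(result.exclusions["reason"].tolist())


class TestRangeFilter:
    def test_exclusive_bounds_drop_tails(self):
        cohort = build_cohort([("A", 0, 33), ("A", 10, 80), ("A", 20, 320)])
        kept = range_filter(cohort.weights, 34, 318)
        assert sorted(kept.weight_kg) == [80.0]

    def test_boundary_semantics(self):
        df = build_cohort([("A", 0, 32)]).weights
        # exclusion rule "<32 or >318": 32 survives
        assert len(range_filter(df, 32, 318, True, True)) == 1
        # inclusive exclusion "<=32 or >=318": 32 is dropped
        assert len(range_filter(df, 32, 318, False, False)) == 0


class TestButa:
    def test_single_measure_patient_fully_excluded(self):
        cohort = build_cohort([("A", 0, 90)], heights={"A": 1.75})
        res = clean_buta(cohort)
        assert res.n_retained == 0
        assert reasons(res) == ["too_few_measures"]

    def test_bmi_out_of_range(self):
        # 200 / 1.2^2 = 138.9 > 70
        cohort = build_cohort(
            [("A", 0, 200), ("A", 10, 80)], heights={"A": 1.2}
        )
        res = clean_buta(cohort)
        assert retained_weights(res) == [80.0]
        assert "bmi_out_of_range" in reasons(res)

    def test_in_range_untouched(self):
        cohort = build_cohort([("A", 0, 80), ("A", 10, 82)], heights={"A": 1.75})
        res = clean_buta(cohort)
        assert retained_weights(res) == [80.0, 82.0]

    def test_no_height_skips_bmi_and_flags(self):
        cohort = build_cohort([("A", 0, 200), ("A", 10, 500)], heights={})
        res = clean_buta(cohort)
        assert res.n_retained == 2
        assert res.flags["no_height_patients"] == ["A"]


class TestChanRaffa:
    def test_cutoff_then_sd(self):
        cohort = build_cohort(
            [("A", d, w) for d, w in [(0, 100), (1, 101), (2, 99), (3, 400)]]
        )
        res = clean_chan_raffa(cohort)
        assert retained_weights(res) == [99.0, 100.0, 101.0]
        assert reasons(res) == ["above_cutoff"]

    def test_constant_weights_all_retained(self):
        cohort = build_cohort([("A", d, 90) for d in range(5)])
        assert clean_chan_raffa(cohort).n_retained == 5

    def test_below_cutoff(self):
        res = clean_chan_raffa(build_cohort([("A", 0, 22)]))
        assert res.n_retained == 0
        assert reasons(res) == ["below_cutoff"]

    def test_fewer_than_three_records_skip_sd_step(self):
        cohort = build_cohort([("A", 0, 50), ("A", 1, 200)])
        assert clean_chan_raffa(cohort).n_retained == 2

    def test_cohort_scope_switch(self):
        entries = [("A", d, 90) for d in range(15)] + [("B", 0, 91), ("B", 1, 330)]
        cohort = build_cohort(entries)
        res = clean_chan_raffa(cohort, AllDataConfig(chan_sd_scope="cohort"))
        assert 330.0 not in retained_weights(res)
        # within-patient default keeps it: B has only 2 records
        assert 330.0 in retained_weights(clean_chan_raffa(cohort))


class TestLongitudinalTrend:
    def test_exact_lines_give_zero_residuals(self):
        entries = []
        for i, (a, b) in enumerate([(80, 2), (95, -3), (110, 0)]):
            for day in (-300, -100, 100, 300):
                entries.append((f"P{i}", day, a + b * day / 365))
        cohort = build_cohort(entries)
        # per-patient OLS reproduces exact lines to machine precision
        trend = fit_longitudinal_trend(cohort.weights, method="ols")
        assert np.abs(trend.residuals.to_numpy()).max() < 1e-9
        # the mixed model converges to the same answer within its optimizer
        # tolerance (variance components at the boundary for zero noise)
        trend = fit_longitudinal_trend(cohort.weights)
        assert trend.method == "mixed"
        assert np.abs(trend.residuals.to_numpy()).max() < 1e-3

    def test_spike_on_exact_line_has_large_residual(self):
        entries = []
        for i in range(10):
            for day in (-300, -150, 0, 150, 300):
                entries.append((f"P{i}", day, 90 + i + 1.0 * day / 365))
        cohort = build_cohort(entries)
        spiked = cohort.weights.copy()
        spiked.loc[2, "weight_kg"] += 25.0  # one visit of P0
        trend = fit_longitudinal_trend(spiked)
        rid = spiked.loc[2, "record_id"]
        assert abs(trend.residuals.loc[rid]) >= 10.0

    def test_degenerate_input_falls_back(self):
        cohort = build_cohort([("A", 0, 90), ("A", 100, 95)])
        trend = fit_longitudinal_trend(cohort.weights)
        assert trend.method == "ols_fallback"
        assert np.abs(trend.residuals.to_numpy()).max() < 1e-9


class TestMaguen:
    def _line_cohort(self, spike=False):
        entries = []
        for i in range(8):
            for day in (-300, -150, 0, 150, 300):
                entries.append((f"P{i}", day, 85 + 2 * i + 1.5 * day / 365))
        cohort = build_cohort(entries)
        if spike:
            cohort.weights.loc[7, "weight_kg"] += 25.0
        return cohort

    def test_spike_removed_exactly(self):
        cohort = self._line_cohort(spike=True)
        res = clean_maguen(cohort)
        excluded = set(res.exclusions.record_id)
        assert excluded == {7}

    def test_clean_lines_untouched(self):
        res = clean_maguen(self._line_cohort())
        assert len(res.exclusions) == 0

    def test_cutoff_applies_regardless_of_fit(self):
        cohort = build_cohort([("A", 0, 320), ("A", 10, 90), ("B", 0, 85), ("B", 20, 86)])
        res = clean_maguen(cohort)
        assert 320.0 not in retained_weights(res)
        assert "above_cutoff" in reasons(res)


class TestBreland:
    def test_isolated_spike_removed(self):
        cohort = build_cohort([("A", 0, 100), ("A", 10, 160), ("A", 20, 100)])
        res = clean_breland(cohort)
        assert retained_weights(res) == [100.0, 100.0]
        assert reasons(res) == ["ratio_outlier"]

    def test_ratio_exactly_at_bound_survives(self):
        cohort = build_cohort([("A", 0, 100), ("A", 10, 150), ("A", 20, 100)])
        assert clean_breland(cohort).n_retained == 3

    def test_cutoff_only(self):
        cohort = build_cohort([("A", 0, 33), ("A", 10, 100)])
        res = clean_breland(cohort)
        assert retained_weights(res) == [100.0]
        assert reasons(res) == ["below_cutoff"]

    def test_endpoint_uses_single_neighbor(self):
        cohort = build_cohort([("A", 0, 200), ("A", 10, 100), ("A", 20, 101)])
        res = clean_breland(cohort)
        assert retained_weights(res) == [100.0, 101.0]


class TestMaciejewski:
    def test_spike_in_constant_series(self):
        entries = [("A", d, 100) for d in range(5)]
        entries += [("A", 5, 180)]
        entries += [("A", d, 100) for d in range(6, 11)]
        res = clean_maciejewski(build_cohort(entries))
        assert retained_weights(res) == [100.0] * 10
        assert reasons(res) == ["rolling_sd_outlier"]

    def test_constant_series_untouched(self):
        res = clean_maciejewski(build_cohort([("A", d, 90) for d in range(8)]))
        assert res.n_retained == 8

    def test_short_series_passed_through(self):
        res = clean_maciejewski(build_cohort([("A", 0, 50), ("A", 1, 500), ("A", 2, 60)]))
        assert res.n_retained == 3


class TestLittman:
    def test_cutoff_then_low_cv_untouched(self):
        res = clean_littman(build_cohort([("A", 0, 33), ("A", 1, 80), ("A", 2, 84)]))
        assert retained_weights(res) == [80.0, 84.0]
        assert reasons(res) == ["below_cutoff"]

    def test_strict_inequality_boundary(self):
        # mean 100, SD 40: CV 40% fires the gate, but |dev| = 40 is not > 40
        res = clean_littman(build_cohort([("A", 0, 60), ("A", 1, 100), ("A", 2, 140)]))
        assert res.n_retained == 3
        # mean 100, SD 50: deviations of exactly 50 are kept too
        res = clean_littman(build_cohort([("A", 0, 50), ("A", 1, 100), ("A", 2, 150)]))
        assert res.n_retained == 3

    def test_deviation_removed_when_cv_high(self):
        # mean 105, SD ~28.6 > 10.5; the 190 deviates by 64 > SD... use clear case
        res = clean_littman(build_cohort(
            [("A", 0, 90), ("A", 1, 92), ("A", 2, 91), ("A", 3, 190)]
        ))
        assert 190.0 not in retained_weights(res)
        assert "cv_outlier" in reasons(res)
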