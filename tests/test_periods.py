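"""Unit tests for the six period-specific cleaning rules."""

import pandas as pd
import pytest

from weightclean import PeriodConfig
from weightclean.periods import (
    clean_goodrich,
    clean_jackson,
    clean_janney,
    clean_kazerooni_lim,
    clean_noel,
    clean_rosenberger,
    fiscal_quarter,
    select_window,
)

from conftest import build_cohort


def retained_weights(result):
    return sorted(result.retained["weight_kg"].tolist())


def reasons(result):
    return sorted(result.exclusions["reason"].unique().tolist())


class TestSelectWindow:
    def test_closed_interval_boundaries(self):
        cohort = build_cohort([("A", 90, 80), ("A", 91, 81), ("A", -90, 82)])
        win = select_window(cohort.weights, 0, 90)
        assert sorted(win.day_offset) == [-90, 90]

    def test_empty_input(self):
        cohort = build_cohort([("A", 0, 80)])
        assert len(select_window(cohort.weights.iloc[0:0], 0, 90)) == 0


class TestRosenberger:
    def test_min_measures(self):
        res = clean_rosenberger(build_cohort([("A", 0, 90)]))
        assert res.n_retained == 0
        assert "too_few_measures" in reasons(res)

    def test_zero_kg_retained_inside_window(self):
        res = clean_rosenberger(build_cohort([("A", 0, 0.0), ("A", 5, 90)]))
        assert 0.0 in retained_weights(res)

    def test_outside_all_windows_excluded(self):
        res = clean_rosenberger(build_cohort([("A", 100, 90), ("A", 3, 91)]))
        assert retained_weights(res) == [91.0]
        assert "outside_period_window" in reasons(res)

    def test_six_month_anchors_span_whole_window(self):
        # day -546 = -3 x 182: an anchor before the index date
        res = clean_rosenberger(build_cohort([("A", -546, 88), ("A", 360, 90)]))
        assert retained_weights(res) == [88.0, 90.0]


class TestNoel:
    def test_quarter_median(self):
        res = clean_noel(build_cohort([("A", 0, 90), ("A", 5, 92), ("A", 10, 94)]))
        assert res.aggregated
        assert retained_weights(res) == [92.0]
        assert res.retained["n_contributing"].tolist() == [3]

    def test_inclusive_cutoff(self):
        res = clean_noel(build_cohort([("A", 0, 318.0), ("A", 5, 32.0), ("A", 10, 90.0)]))
        assert retained_weights(res) == [90.0]
        assert set(reasons(res)) == {"above_cutoff", "below_cutoff"}

    def test_fiscal_quarter_labels(self):
        dates = pd.Series(pd.to_datetime(["2016-10-01", "2016-12-31", "2017-01-15", "2017-09-30"]))
        assert fiscal_quarter(dates).tolist() == ["FY2017Q1", "FY2017Q1", "FY2017Q2", "FY2017Q4"]
        assert fiscal_quarter(dates, start_month=1).tolist() == [
            "FY2016Q4", "FY2016Q4", "FY2017Q1", "FY2017Q3"]

    def test_quarter_with_no_survivors_emits_nothing(self):
        res = clean_noel(build_cohort([("A", 0, 320.0)]))
        assert res.n_retained == 0


class TestKazerooniLim:
    def test_missing_period_drops_patient(self):
        res = clean_kazerooni_lim(
            build_cohort([("A", 0, 90), ("A", 180, 91)])  # no 12-month record
        )
        assert res.n_retained == 0
        assert "missing_period" in reasons(res)

    def test_complete_patient_keeps_all_three(self):
        res = clean_kazerooni_lim(
            build_cohort([("A", -10, 90), ("A", 182, 91), ("A", 390, 92)])
        )
        assert retained_weights(res) == [90.0, 91.0, 92.0]

    def test_no_value_cutoffs(self):
        res = clean_kazerooni_lim(
            build_cohort([("A", 0, 559.0), ("A", 182, 91), ("A", 365, 92)])
        )
        assert 559.0 in retained_weights(res)


class TestJackson:
    def test_window_mean(self):
        res = clean_jackson(build_cohort([("A", -10, 100), ("A", 5, 102)]))
        base = res.retained[res.retained.period == "day0"]
        assert base.weight_kg.tolist() == [101.0]
        assert base.n_contributing.tolist() == [2]

    def test_single_weight_aggregate_equals_it(self):
        res = clean_jackson(build_cohort([("A", 182, 88)]))
        assert retained_weights(res) == [88.0]

    def test_cutoff_before_averaging(self):
        res = clean_jackson(build_cohort([("A", 0, 33), ("A", 5, 100)]))
        assert retained_weights(res) == [100.0]
        assert "below_cutoff" in reasons(res)


class TestGoodrich:
    def test_implausible_change_drops_patient(self):
        res = clean_goodrich(build_cohort([("A", 0, 100), ("A", 182, 160)]))
        assert res.n_retained == 0
        assert "implausible_change" in reasons(res)

    def test_change_under_cap_retained(self):
        res = clean_goodrich(build_cohort([("A", 0, 100), ("A", 182, 140)]))
        assert retained_weights(res) == [100.0, 140.0]

    def test_cutoff(self):
        res = clean_goodrich(build_cohort([("A", 0, 230), ("A", 182, 90)]))
        assert retained_weights(res) == [90.0]
        assert "above_cutoff" in reasons(res)

    def test_closest_record_selected_tie_to_earlier(self):
        res = clean_goodrich(
            build_cohort([("A", -3, 95), ("A", 3, 96), ("A", 10, 97)])
        )
        assert retained_weights(res) == [95.0]


class TestJanney:
    def test_baseline_cutoff_only_at_baseline(self):
        res = clean_janney(build_cohort([("A", 0, 40), ("A", 182, 90)]))
        assert 40.0 not in retained_weights(res)
        assert "below_cutoff" in reasons(res)
        # same weight at a follow-up anchor is not cutoff-filtered
        res2 = clean_janney(build_cohort([("A", 0, 90), ("A", 182, 60)]))
        assert 60.0 in retained_weights(res2)

    def test_followup_window_is_60_days(self):
        res = clean_janney(build_cohort([("A", 0, 90), ("A", 182 + 45, 91)]))
        assert retained_weights(res) == [90.0, 91.0]
        # 45 days off baseline is outside its 30-day window
        res2 = clean_janney(build_cohort([("A", 45, 90), ("A", 182, 91)]))
        assert 90.0 not in retained_weights(res2)

    def test_change_rule_drops_later_record(self):
        res = clean_janney(
            build_cohort([("A", 0, 100), ("A", 182, 80), ("A", 365, 150)])
        )
        assert retained_weights(res) == [80.0, 100.0]
        assert "implausible_change" in reasons(res)


class TestAggregateInvariants:
    def test_aggregates_bounded_by_contributors(self, rng):
        from conftest import random_mini_cohort

        for _ in range(30):
            cohort = random_mini_cohort(rng)
            for clean in (clean_jackson, clean_noel):
                res = clean(cohort)
                for row in res.retained.itertuples():
                    # reconstruct contributors from the input
                    contrib = cohort.weights[
                        cohort.weights.patient_id == row.patient_id
                    ]["weight_kg"]
                    assert contrib.min() - 1e-9 <= row.weight_kg <= contrib.max() + 1e-9
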