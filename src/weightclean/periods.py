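"""The six period-specific cleaning algorithms.

These rules anchor on baseline / 6-month / 12-month time points (or fiscal
quarters) and select or aggregate measurements inside closed windows around
them.  Two of them aggregate — ``jackson`` (window means) and ``noel``
(fiscal-quarter medians) — and emit one row per patient-period instead of a
subset of the input records; the rest select records and keep the usual
retained/excluded partition.

Window and tie conventions: all windows are closed day intervals;
"closest to anchor" ties break toward the earlier date, then the lower
record id.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PeriodConfig
from .records import Cohort
from .result import AGGREGATE_COLUMNS, CleanResult, ExclusionLog
from .allmeasures import range_filter

__all__ = [
    "select_window",
    "clean_rosenberger",
    "clean_noel",
    "clean_kazerooni_lim",
    "clean_jackson",
    "clean_goodrich",
    "clean_janney",
    "fiscal_quarter",
]


def select_window(
    records: pd.DataFrame, anchor_day: int, window_days: int
) -> pd.DataFrame:
    """Records with |day_offset - anchor_day| <= window_days (closed)."""
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    return records[(records["day_offset"] - anchor_day).abs() <= window_days]


def _in_any_window(
    records: pd.DataFrame, anchors: Sequence[int], window_days: int
) -> pd.Series:
    day = records["day_offset"]
    mask = pd.Series(False, index=records.index)
    for a in anchors:
        mask |= (day - a).abs() <= window_days
    return mask


def _closest_per_patient(window_records: pd.DataFrame, anchor_day: int) -> pd.DataFrame:
    """One record per patient: minimal |day - anchor|, ties to earlier day,
    then lower record_id."""
    wr = window_records.copy()
    wr["_dist"] = (wr["day_offset"] - anchor_day).abs()
    wr = wr.sort_values(["_dist", "day_offset", "record_id"], kind="stable")
    sel = wr.drop_duplicates("patient_id", keep="first").drop(columns="_dist")
    return sel


def clean_rosenberger(
    cohort: Cohort, config: PeriodConfig = PeriodConfig()
) -> CleanResult:
    """Minimum-measure-count filter plus 6-month time-point windows.

    Patients with fewer than K total measures are dropped; the rest keep
    only records within the window of anchors spaced every 6 months across
    the full collection window.  No value cutoffs — implausible values such
    as 0 kg survive if they land in a window.
    """
    records = cohort.weights
    log = ExclusionLog()

    counts = records.groupby("patient_id")["record_id"].transform("size")
    few = counts < config.rosenberger_min_measures
    log.add(records[few], "too_few_measures", 1)
    kept = records[~few]

    if config.rosenberger_full_window:
        lo, hi = cohort.collection_window_days
        sp = config.rosenberger_spacing_days
        anchors = [k * sp for k in range(int(np.ceil(lo / sp)), int(np.floor(hi / sp)) + 1)]
    else:
        anchors = list(config.anchors_days)
    inwin = _in_any_window(kept, anchors, config.rosenberger_window_days)
    log.add(kept[~inwin], "outside_period_window", 2)
    return CleanResult.build("rosenberger", kept[inwin], log, config)


def fiscal_quarter(dates: pd.Series, start_month: int = 10) -> pd.Series:
    """Label each date with its fiscal quarter, e.g. ``FY2017Q1``.

    The fiscal year is named for the calendar year it ends in (October 2016
    is FY2017Q1 under the default October start).
    """
    months_since_start = (dates.dt.month - start_month) % 12
    q = months_since_start // 3 + 1
    fy = dates.dt.year + ((dates.dt.month >= start_month) & (start_month > 1)).astype(int)
    return "FY" + fy.astype(str) + "Q" + q.astype(str)


def _quarter_midpoint(dates: pd.Series, start_month: int) -> pd.Series:
    """Midpoint date of each record's fiscal quarter (start + 45 days)."""
    months_since_start = (dates.dt.month - start_month) % 12
    qstart_month = (dates.dt.month - months_since_start % 3 - 1) % 12 + 1
    year = dates.dt.year - ((dates.dt.month - months_since_start % 3) < 1).astype(int)
    qstart = pd.to_datetime(
        pd.DataFrame({"year": year, "month": qstart_month, "day": 1}, index=dates.index)
    )
    return qstart + pd.Timedelta(days=45)


def clean_noel(cohort: Cohort, config: PeriodConfig = PeriodConfig()) -> CleanResult:
    """Inclusive cutoffs then fiscal-quarter medians (aggregating).

    Weights at or beyond the cutoffs (``<=32`` or ``>=318`` kg by default)
    are excluded; each survivor is assigned to its fiscal quarter and every
    patient-quarter with at least ``noel_min_per_quarter`` values emits its
    median as one aggregated weight, anchored at the quarter midpoint.
    """
    log = ExclusionLog()
    lo, hi = config.noel_cutoffs_kg
    kept = range_filter(
        cohort.weights, lo, hi, low_inclusive=False, high_inclusive=False,
        log=log, step=1,
    )

    if len(kept) == 0:
        agg = pd.DataFrame(columns=AGGREGATE_COLUMNS)
        return CleanResult.build("noel", agg, log, config, aggregated=True)

    kept = kept.copy()
    kept["period"] = fiscal_quarter(kept["date"], config.fiscal_year_start_month)
    mid = _quarter_midpoint(kept["date"], config.fiscal_year_start_month)
    index_dates = cohort.patients.set_index("patient_id")["index_date"]
    kept["_mid_day"] = (mid - kept["patient_id"].map(index_dates)).dt.days

    groups = kept.groupby(["patient_id", "period"])
    agg = groups.agg(
        weight_kg=("weight_kg", "median"),
        n_contributing=("weight_kg", "size"),
        day_offset=("_mid_day", "first"),
    ).reset_index()
    sparse = agg["n_contributing"] < config.noel_min_per_quarter
    if sparse.any():
        thin = agg[sparse]
        drop = kept.merge(thin[["patient_id", "period"]], on=["patient_id", "period"])
        log.add(drop, "too_few_in_quarter", 2)
        agg = agg[~sparse]
    agg["aggregation"] = "median"
    agg = agg[AGGREGATE_COLUMNS].sort_values(["patient_id", "day_offset"], kind="stable")
    return CleanResult.build("noel", agg, log, config, aggregated=True)


def clean_kazerooni_lim(
    cohort: Cohort, config: PeriodConfig = PeriodConfig()
) -> CleanResult:
    """Three-period windows plus a complete-data requirement.

    Records within the window of any of the three anchors are candidates;
    patients lacking at least one record in *every* period lose all their
    candidate records.  No value cutoffs — this rule retains any value that
    lands in its windows, however implausible.
    """
    records = cohort.weights
    log = ExclusionLog()
    anchors = list(config.anchors_days)
    w = config.kazerooni_window_days

    inwin = _in_any_window(records, anchors, w)
    log.add(records[~inwin], "outside_period_window", 1)
    kept = records[inwin]

    complete = None
    for a in anchors:
        covered = set(select_window(kept, a, w)["patient_id"])
        complete = covered if complete is None else complete & covered
    incomplete = ~kept["patient_id"].isin(complete or set())
    log.add(kept[incomplete], "missing_period", 2)
    return CleanResult.build("kazerooni_lim", kept[~incomplete], log, config)


def clean_jackson(cohort: Cohort, config: PeriodConfig = PeriodConfig()) -> CleanResult:
    """Cutoffs then per-anchor window means (aggregating).

    After the (34, 318) kg cutoff step, each anchor's 90-day window mean is
    emitted per patient; anchors with no surviving records emit nothing.
    Records outside every window are logged; in-window records are consumed
    by their aggregate.
    """
    log = ExclusionLog()
    lo, hi = config.jackson_cutoffs_kg
    kept = range_filter(cohort.weights, lo, hi, log=log, step=1)

    parts: List[pd.DataFrame] = []
    consumed = pd.Series(False, index=kept.index)
    for a in config.anchors_days:
        inwin = (kept["day_offset"] - a).abs() <= config.jackson_window_days
        consumed |= inwin
        win = kept[inwin]
        if len(win) == 0:
            continue
        agg = (
            win.groupby("patient_id")
            .agg(weight_kg=("weight_kg", "mean"), n_contributing=("weight_kg", "size"))
            .reset_index()
        )
        agg["period"] = f"day{a}"
        agg["day_offset"] = a
        parts.append(agg)
    log.add(kept[~consumed], "outside_period_window", 2)
    if parts:
        agg = pd.concat(parts, ignore_index=True)
        agg["aggregation"] = "mean"
        agg = agg[AGGREGATE_COLUMNS].sort_values(
            ["patient_id", "day_offset"], kind="stable"
        )
    else:
        agg = pd.DataFrame(columns=AGGREGATE_COLUMNS)
    return CleanResult.build("jackson", agg, log, config, aggregated=True)


def _select_by_anchor(
    kept: pd.DataFrame,
    anchors: Sequence[int],
    windows: Sequence[int],
    log: ExclusionLog,
    step: int,
) -> pd.DataFrame:
    """Closest record per patient per anchor; log everything not selected.

    Returns the selected records with an ``_anchor`` column, ordered by
    (patient, anchor).
    """
    selected_parts = []
    in_any = pd.Series(False, index=kept.index)
    for a, w in zip(anchors, windows):
        inwin = (kept["day_offset"] - a).abs() <= w
        in_any |= inwin
        sel = _closest_per_patient(kept[inwin], a)
        sel = sel.copy()
        sel["_anchor"] = a
        selected_parts.append(sel)
    log.add(kept[~in_any], "outside_period_window", step)
    selected = (
        pd.concat(selected_parts, ignore_index=True)
        if selected_parts
        else kept.iloc[0:0].assign(_anchor=pd.Series(dtype=int))
    )
    leftover = kept[in_any & ~kept["record_id"].isin(selected["record_id"])]
    log.add(leftover, "not_selected_in_window", step)
    return selected.sort_values(["patient_id", "_anchor"], kind="stable")


def clean_goodrich(cohort: Cohort, config: PeriodConfig = PeriodConfig()) -> CleanResult:
    """Cutoffs, closest-record selection, and a patient-level change cap.

    After the (36, 227) kg cutoffs, the record closest to each anchor
    within its 30-day window is selected; any patient whose selected series
    changes by more than 45 kg between consecutive periods is removed
    entirely.
    """
    log = ExclusionLog()
    lo, hi = config.goodrich_cutoffs_kg
    kept = range_filter(cohort.weights, lo, hi, log=log, step=1)

    windows = [config.goodrich_window_days] * len(config.anchors_days)
    selected = _select_by_anchor(kept, config.anchors_days, windows, log, step=2)

    diffs = selected.groupby("patient_id")["weight_kg"].diff().abs()
    bad_patients = set(selected.loc[diffs > config.change_cap_kg, "patient_id"])
    out = selected["patient_id"].isin(bad_patients)
    log.add(selected[out], "implausible_change", 3)
    retained = (
        selected[~out]
        .drop(columns="_anchor")
        .drop_duplicates("record_id")
        .sort_values("record_id", kind="stable")
    )
    return CleanResult.build("goodrich", retained, log, config)


def clean_janney(cohort: Cohort, config: PeriodConfig = PeriodConfig()) -> CleanResult:
    """Baseline cutoffs, 30/60/60-day selection, record-level change cap.

    The (41, 272) kg cutoff applies only to records in the baseline window;
    windows are 30 days at baseline and 60 days at the follow-up anchors,
    with the closest record selected per anchor.  Walking the selected
    series in time order, a record producing a change greater than 45 kg
    from the last kept selection is excluded (the later record of the
    offending pair), and the walk continues from the kept one.
    """
    records = cohort.weights
    log = ExclusionLog()

    anchors = list(config.anchors_days)
    windows = list(config.janney_window_days)
    base_win = (records["day_offset"] - anchors[0]).abs() <= windows[0]
    lo, hi = config.janney_baseline_cutoffs_kg
    below = base_win & (records["weight_kg"] < lo)
    above = base_win & (records["weight_kg"] > hi)
    log.add(records[below], "below_cutoff", 1)
    log.add(records[above], "above_cutoff", 1)
    kept = records[~below & ~above]

    selected = _select_by_anchor(kept, anchors, windows, log, step=2)

    drop_ids = []
    for _, grp in selected.groupby("patient_id", sort=False):
        last = None
        for rid, w in zip(grp["record_id"].to_numpy(), grp["weight_kg"].to_numpy()):
            if last is not None and abs(w - last) > config.change_cap_kg:
                drop_ids.append(rid)
                continue
            last = w
    out = selected["record_id"].isin(drop_ids)
    log.add(selected[out], "implausible_change", 3)
    retained = (
        selected[~out]
        .drop(columns="_anchor")
        .drop_duplicates("record_id")
        .sort_values("record_id", kind="stable")
    )
    return CleanResult.build("janney", retained, log, config)
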