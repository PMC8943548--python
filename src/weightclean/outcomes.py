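"""Downstream measures used to compare cleaning algorithms.

Baseline-weight extraction around the index date, 1-year >=5% weight
change, unadjusted facility-level loss/gain rates with rankings, and a
single-predictor logistic harness (weight -> binary outcome).

The >=5% thresholds are inclusive: a percent change of exactly -5.0
classifies as loss, exactly +5.0 as gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .result import CleanResult

__all__ = [
    "extract_baseline_weight",
    "compute_weight_change",
    "weight_change_table",
    "WeightChangeOutcome",
    "facility_rates",
    "fit_binary_outcome_model",
    "BinaryOutcomeModelResult",
]


def _measures(clean_result: CleanResult) -> pd.DataFrame:
    """Record-level or aggregate-level measures with a day axis.

    Aggregates are anchored at their period's day (anchor day or fiscal
    quarter midpoint), so window extraction treats both shapes uniformly.
    """
    df = clean_result.retained
    cols = ["patient_id", "day_offset", "weight_kg"]
    if clean_result.aggregated:
        out = df[cols].copy()
        out["_tiebreak"] = np.arange(len(out))
        return out
    out = df[cols].copy()
    out["_tiebreak"] = df["record_id"].to_numpy()
    return out


def _closest_in_window(
    measures: pd.DataFrame, anchor_day: int, half_window_days: int
) -> pd.DataFrame:
    """Per patient, the measure on the day closest to the anchor within the
    window; ties go to the earlier day, then the lower record id."""
    m = measures[(measures["day_offset"] - anchor_day).abs() <= half_window_days].copy()
    m["_dist"] = (m["day_offset"] - anchor_day).abs()
    m = m.sort_values(["_dist", "day_offset", "_tiebreak"], kind="stable")
    return m.drop_duplicates("patient_id", keep="first")


def extract_baseline_weight(
    clean_result: CleanResult,
    patient_id,
    index_day: int = 0,
    half_window_days: int = 30,
) -> Optional[Tuple[float, int]]:
    """Baseline weight for one patient: the cleaned measurement on the day
    closest to the index within ±half_window_days, or ``None``."""
    m = _measures(clean_result)
    m = m[m["patient_id"] == patient_id]
    sel = _closest_in_window(m, index_day, half_window_days)
    if len(sel) == 0:
        return None
    row = sel.iloc[0]
    return float(row["weight_kg"]), int(row["day_offset"])


@dataclass(frozen=True)
class WeightChangeOutcome:
    patient_id: object
    baseline_kg: Optional[float]
    followup_kg: Optional[float]
    delta_kg: Optional[float]
    pct_change: Optional[float]
    classification: str  # loss_ge_5 | gain_ge_5 | neither | missing


def _classify(pct: float) -> str:
    if pct <= -5.0:
        return "loss_ge_5"
    if pct >= 5.0:
        return "gain_ge_5"
    return "neither"


def compute_weight_change(
    clean_result: CleanResult,
    patient_id,
    index_day: int = 0,
    horizon_days: int = 365,
    half_window_days: int = 60,
) -> WeightChangeOutcome:
    """One patient's 1-year weight change and >=5% classification.

    Baseline and follow-up are each the closest cleaned measurement within
    ±half_window_days of the index day and of index + horizon; the outcome
    is ``missing`` when either endpoint is absent (or baseline is 0 kg,
    which would make percent change undefined).
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    base = extract_baseline_weight(clean_result, patient_id, index_day, half_window_days)
    fup = extract_baseline_weight(
        clean_result, patient_id, index_day + horizon_days, half_window_days
    )
    if base is None or fup is None or base[0] == 0.0:
        b = base[0] if base else None
        f = fup[0] if fup else None
        return WeightChangeOutcome(patient_id, b, f, None, None, "missing")
    delta = fup[0] - base[0]
    pct = 100.0 * delta / base[0]
    return WeightChangeOutcome(patient_id, base[0], fup[0], delta, pct, _classify(pct))


def weight_change_table(
    clean_result: CleanResult,
    patient_ids: Optional[Sequence] = None,
    index_day: int = 0,
    horizon_days: int = 365,
    half_window_days: int = 60,
) -> pd.DataFrame:
    """Vectorized :func:`compute_weight_change` over a whole cohort.

    Returns one row per patient: ``patient_id, baseline_kg, followup_kg,
    delta_kg, pct_change, classification``.
    """
    m = _measures(clean_result)
    base = _closest_in_window(m, index_day, half_window_days).set_index("patient_id")
    fup = _closest_in_window(m, index_day + horizon_days, half_window_days).set_index(
        "patient_id"
    )
    if patient_ids is None:
        patient_ids = m["patient_id"].unique()
    out = pd.DataFrame({"patient_id": list(patient_ids)})
    out["baseline_kg"] = out["patient_id"].map(base["weight_kg"])
    out["followup_kg"] = out["patient_id"].map(fup["weight_kg"])
    ok = out["baseline_kg"].notna() & out["followup_kg"].notna() & (out["baseline_kg"] != 0)
    out["delta_kg"] = np.where(ok, out["followup_kg"] - out["baseline_kg"], np.nan)
    with np.errstate(invalid="ignore"):
        out["pct_change"] = np.where(ok, 100.0 * out["delta_kg"] / out["baseline_kg"], np.nan)
    cls = np.full(len(out), "missing", dtype=object)
    cls[(out["pct_change"] <= -5.0).to_numpy()] = "loss_ge_5"
    cls[(out["pct_change"] >= 5.0).to_numpy()] = "gain_ge_5"
    neither = ok & (out["pct_change"] > -5.0) & (out["pct_change"] < 5.0)
    cls[neither.to_numpy()] = "neither"
    out["classification"] = cls
    return out


def facility_rates(
    outcomes: pd.DataFrame, facility_by_patient: Dict
) -> pd.DataFrame:
    """Unadjusted per-facility >=5% loss/gain rates with rankings.

    `outcomes` is a :func:`weight_change_table` frame.  Eligible patients
    are those with a non-missing outcome; percentages are out of eligible.
    Ranks are assigned descending by percentage (rank 1 = highest rate),
    ties broken by facility id; facilities with zero eligible patients are
    flagged and left unranked.
    """
    df = outcomes.copy()
    df["facility_id"] = df["patient_id"].map(facility_by_patient)
    if df["facility_id"].isna().any():
        missing = df.loc[df["facility_id"].isna(), "patient_id"].head().tolist()
        raise ValueError(f"patients without a facility assignment: {missing}")
    eligible = df[df["classification"] != "missing"]
    summary = (
        df.groupby("facility_id")
        .agg(n_patients=("patient_id", "size"))
        .reset_index()
    )
    agg = (
        eligible.groupby("facility_id")
        .agg(
            n_eligible=("patient_id", "size"),
            n_loss=("classification", lambda c: int((c == "loss_ge_5").sum())),
            n_gain=("classification", lambda c: int((c == "gain_ge_5").sum())),
        )
        .reset_index()
    )
    summary = summary.merge(agg, on="facility_id", how="left")
    summary["n_eligible"] = summary["n_eligible"].fillna(0).astype(int)
    for c in ("n_loss", "n_gain"):
        summary[c] = summary[c].fillna(0).astype(int)
    has = summary["n_eligible"] > 0
    summary["pct_loss"] = np.where(has, 100.0 * summary["n_loss"] / summary["n_eligible"].where(has, 1), np.nan)
    summary["pct_gain"] = np.where(has, 100.0 * summary["n_gain"] / summary["n_eligible"].where(has, 1), np.nan)
    summary["flag"] = np.where(has, "", "no_eligible_patients")

    for metric in ("loss", "gain"):
        ranked = summary[has].sort_values(
            [f"pct_{metric}", "facility_id"], ascending=[False, True], kind="stable"
        )
        ranks = pd.Series(
            np.arange(1, len(ranked) + 1), index=ranked.index, dtype=float
        )
        summary[f"rank_{metric}"] = ranks.reindex(summary.index)
    return summary


@dataclass(frozen=True)
class BinaryOutcomeModelResult:
    """Per-kilogram odds ratio with a Wald 95% confidence interval."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    n_used: int
    intercept: float


def fit_binary_outcome_model(
    baseline_kg: Sequence[float], outcome: Sequence[bool]
) -> BinaryOutcomeModelResult:
    """Logistic regression of a binary outcome on baseline weight.

    Single predictor plus intercept.  Raises ``ValueError`` for degenerate
    outcomes (one class only), fewer than 10 observations, or complete
    separation.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    w = np.asarray(baseline_kg, dtype=float)
    y = np.asarray(outcome, dtype=float)
    keep = ~np.isnan(w) & ~np.isnan(y)
    w, y = w[keep], y[keep]
    if len(w) < 10:
        raise ValueError(f"need >= 10 observations, got {len(w)}")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate outcome: only one class present")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, sm.add_constant(w)).fit(disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError) as exc:
        raise ValueError(f"complete separation or singular design: {exc}") from exc
    beta = fit.params[1]
    se = fit.bse[1]
    if not np.isfinite(se) or se > 1e3:
        raise ValueError("complete separation: unbounded standard error")
    z = 1.959963984540054
    return BinaryOutcomeModelResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        n_used=int(len(w)),
        intercept=float(fit.params[0]),
    )
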