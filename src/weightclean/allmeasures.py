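"""The six cleaning algorithms that use all weight measures in the window.

Each function maps a :class:`~weightclean.records.Cohort` to a
:class:`~weightclean.result.CleanResult`.  The rules, named after the lead
author of the study that introduced them:

* ``buta`` — drop patients with <=1 weight, then BMI plausibility band.
* ``chan_raffa`` — cutoffs (23, 340) kg, then >3 within-patient SDs from
  the within-patient mean.
* ``maguen`` — cutoffs (32, 318) kg, then |conditional residual| >= 10 kg
  from a linear mixed model with random intercept and slope.
* ``breland`` — cutoffs (34, 318) kg, then ratios to temporal neighbors.
* ``maciejewski`` — rolling-window SD rule, no cutoffs.
* ``littman`` — cutoffs (34, 272) kg, then a deviation rule gated by the
  within-patient coefficient of variation.

Within-patient statistics use the sample SD (n-1 denominator); patients
with fewer than two records have no defined SD and skip SD-based steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import AllDataConfig
from .records import Cohort
from .result import CleanResult, ExclusionLog

__all__ = [
    "range_filter",
    "clean_buta",
    "clean_chan_raffa",
    "fit_longitudinal_trend",
    "TrendResiduals",
    "clean_maguen",
    "clean_breland",
    "clean_maciejewski",
    "clean_littman",
]


def range_filter(
    records: pd.DataFrame,
    low_kg: float,
    high_kg: float,
    low_inclusive: bool = True,
    high_inclusive: bool = True,
    log: Optional[ExclusionLog] = None,
    step: int = 1,
) -> pd.DataFrame:
    """Retain records inside a weight interval; shared cutoff helper.

    ``low_inclusive=True`` keeps a weight exactly at the lower bound (the
    exclusion rule is ``< low``); ``False`` drops it (``<= low``).  Same for
    the upper bound.  Excluded records are appended to `log` when given.
    """
    if not low_kg < high_kg:
        raise ValueError("low_kg must be < high_kg")
    w = records["weight_kg"]
    below = w < low_kg if low_inclusive else w <= low_kg
    above = w > high_kg if high_inclusive else w >= high_kg
    if log is not None:
        log.add(records[below], "below_cutoff", step)
        log.add(records[above], "above_cutoff", step)
    return records[~below & ~above]


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) >= 2 else float("nan")


def clean_buta(cohort: Cohort, config: AllDataConfig = AllDataConfig()) -> CleanResult:
    """Patient-level sparsity filter followed by a BMI plausibility band.

    Step 1 removes every record of patients with at most one weight value;
    step 2 removes records whose BMI (from the patient's derived height)
    falls below/above the band.  Patients without a derived height skip the
    BMI step and are listed in ``flags["no_height_patients"]``.
    """
    records = cohort.weights
    log = ExclusionLog()

    counts = records.groupby("patient_id")["record_id"].transform("size")
    few = records[counts <= 1]
    log.add(few, "too_few_measures", 1)
    kept = records[counts > 1].copy()

    heights = kept["patient_id"].map(cohort.heights_by_patient())
    no_height = heights.isna()
    bmi = kept["weight_kg"] / heights**2
    lo, hi = config.buta_bmi_bounds
    out = ~no_height & ((bmi < lo) | (bmi > hi))
    log.add(kept[out], "bmi_out_of_range", 2)
    kept = kept[~out]

    flags = {}
    skipped = sorted(kept.loc[no_height[kept.index], "patient_id"].unique().tolist())
    if skipped:
        flags["no_height_patients"] = skipped
    return CleanResult.build("buta", kept, log, config, flags=flags)


def clean_chan_raffa(
    cohort: Cohort, config: AllDataConfig = AllDataConfig()
) -> CleanResult:
    """Cutoffs then a single-pass 3-SD deviation-from-mean rule.

    The mean and SD are computed once on cutoff survivors — within patient
    by default (patients with fewer than three surviving records skip the
    step), or across the whole cohort with ``chan_sd_scope="cohort"``.
    """
    log = ExclusionLog()
    lo, hi = config.chan_cutoffs_kg
    kept = range_filter(cohort.weights, lo, hi, log=log, step=1)

    k = config.chan_sd_multiplier
    if config.chan_sd_scope == "cohort":
        if len(kept) >= 3:
            mean = kept["weight_kg"].mean()
            sd = _sample_sd(kept["weight_kg"].to_numpy())
            out = (kept["weight_kg"] - mean).abs() > k * sd
            log.add(kept[out], "sd_outlier", 2)
            kept = kept[~out]
    else:
        grp = kept.groupby("patient_id")["weight_kg"]
        n = grp.transform("size")
        mean = grp.transform("mean")
        sd = grp.transform("std")  # sample SD, NaN for n == 1
        out = (n >= 3) & ((kept["weight_kg"] - mean).abs() > k * sd)
        log.add(kept[out], "sd_outlier", 2)
        kept = kept[~out]
    return CleanResult.build("chan_raffa", kept, log, config)


@dataclass
class TrendResiduals:
    """Conditional residuals from a within-patient linear weight trend.

    ``residuals`` is indexed by ``record_id``; ``fixed_effects`` holds the
    population (intercept, slope per year); ``random_effects`` one row per
    patient with intercept/slope deviations (empty for the OLS path);
    ``method`` is ``"mixed"``, ``"ols"`` or ``"ols_fallback"``.
    """

    residuals: pd.Series
    fixed_effects: Tuple[float, float]
    random_effects: pd.DataFrame
    method: str


def _ols_residuals(records: pd.DataFrame) -> pd.Series:
    """Per-patient ordinary least-squares residuals (closed form).

    Patients with one or two records sit exactly on their own line, so
    their residuals are zero; a patient whose visits all fall on one day
    has no slope and deviates from the day's mean.
    """
    t = records["day_offset"].to_numpy(dtype=float) / 365.0
    w = records["weight_kg"].to_numpy(dtype=float)
    df = pd.DataFrame({"pid": records["patient_id"].to_numpy(), "t": t, "w": w})
    g = df.groupby("pid")
    dt = df["t"] - g["t"].transform("mean")
    dw = df["w"] - g["w"].transform("mean")
    df["_xy"] = dt * dw
    df["_xx"] = dt * dt
    g = df.groupby("pid")
    sxx = g["_xx"].transform("sum")
    sxy = g["_xy"].transform("sum")
    slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    resid = dw.to_numpy() - slope * dt.to_numpy()
    return pd.Series(resid, index=pd.Index(records["record_id"], name="record_id"))


def fit_longitudinal_trend(
    records: pd.DataFrame, method: str = "mixed"
) -> TrendResiduals:
    """Fit weight on time and return per-record conditional residuals.

    The mixed path fits a population intercept and slope plus per-patient
    random intercepts and slopes; the conditional residual is the observed
    weight minus the patient-specific fitted value.  Degenerate inputs
    (fewer than two patients with two or more records) or a singular /
    non-converging fit fall back to per-patient OLS lines, and the result
    is flagged ``ols_fallback``.
    """
    if method not in ("mixed", "ols"):
        raise ValueError("method must be 'mixed' or 'ols'")
    sizes = records.groupby("patient_id").size()
    if method == "ols" or (sizes >= 2).sum() < 2 or len(records) < 4:
        res = _ols_residuals(records)
        tag = "ols" if method == "ols" else "ols_fallback"
        return TrendResiduals(res, (float("nan"), float("nan")),
                              pd.DataFrame(columns=["intercept", "slope"]), tag)

    import statsmodels.api as sm

    t = records["day_offset"].to_numpy(dtype=float) / 365.0
    exog = sm.add_constant(t)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                records["weight_kg"].to_numpy(dtype=float),
                exog,
                groups=records["patient_id"].to_numpy(),
                exog_re=exog,
            )
            fit = model.fit(method="lbfgs", reml=True)
        fe = np.asarray(fit.fe_params, dtype=float)
        re = pd.DataFrame(fit.random_effects).T
        re.columns = ["intercept", "slope"]
    except (np.linalg.LinAlgError, ValueError):
        res = _ols_residuals(records)
        return TrendResiduals(res, (float("nan"), float("nan")),
                              pd.DataFrame(columns=["intercept", "slope"]), "ols_fallback")

    pid = records["patient_id"].to_numpy()
    ri = re["intercept"].reindex(pid).to_numpy()
    rs = re["slope"].reindex(pid).to_numpy()
    fitted = fe[0] + fe[1] * t + ri + rs * t
    resid = records["weight_kg"].to_numpy(dtype=float) - fitted
    return TrendResiduals(
        pd.Series(resid, index=pd.Index(records["record_id"], name="record_id")),
        (float(fe[0]), float(fe[1])),
        re,
        "mixed",
    )


def clean_maguen(cohort: Cohort, config: AllDataConfig = AllDataConfig()) -> CleanResult:
    """Cutoffs then a single-pass conditional-residual filter.

    Records whose |conditional residual| meets or exceeds the threshold
    (10 kg by default) are removed; the trend is fitted once on cutoff
    survivors, with no iterative refit.
    """
    log = ExclusionLog()
    lo, hi = config.maguen_cutoffs_kg
    kept = range_filter(cohort.weights, lo, hi, log=log, step=1)

    flags = {}
    if len(kept):
        trend = fit_longitudinal_trend(kept, method=config.maguen_trend_method)
        flags["trend_method"] = trend.method
        resid = trend.residuals.reindex(kept["record_id"]).to_numpy()
        out = np.abs(resid) >= config.maguen_residual_threshold_kg
        log.add(kept[out], "residual_outlier", 2)
        kept = kept[~out]
    return CleanResult.build("maguen", kept, log, config, flags=flags)


def _ratio_outside(w: float, neighbor: float, rlo: float, rhi: float) -> bool:
    if neighbor == 0.0:
        return w != 0.0  # infinite ratio; two zeros count as concordant
    r = w / neighbor
    return r < rlo or r > rhi


def _breland_patient(weights, record_ids, rlo, rhi):
    """Removed record ids for one patient's time-ordered series.

    Iterates to a fixed point: interior records whose ratios to *both*
    neighbors fall outside the bounds are removed first (they are the
    records both neighbors disavow); only when no interior record is
    flagged may a flagged endpoint (single neighbor) be removed.  Each
    removal splices the series, so survivors become neighbors.
    """
    ws = [float(w) for w in weights]
    rids = list(record_ids)
    removed = []
    while len(ws) >= 2:
        n = len(ws)
        flagged = []
        for i in range(n):
            votes = []
            if i > 0:
                votes.append(_ratio_outside(ws[i], ws[i - 1], rlo, rhi))
            if i < n - 1:
                votes.append(_ratio_outside(ws[i], ws[i + 1], rlo, rhi))
            if votes and all(votes):
                flagged.append(i)
        drop = [i for i in flagged if 0 < i < n - 1] or flagged
        if not drop:
            break
        for i in sorted(drop, reverse=True):
            removed.append(rids[i])
            del ws[i], rids[i]
    return removed


def clean_breland(cohort: Cohort, config: AllDataConfig = AllDataConfig()) -> CleanResult:
    """Cutoffs then within-patient neighbor-ratio screening.

    After the cutoff step, each surviving record's ratio to its previous
    and next surviving neighbor in time order is computed; a record is
    removed when every available neighbor ratio falls strictly outside the
    closed bounds (default [2/3, 3/2] — a ratio of exactly 1.5 survives).
    Interior records rejected by both neighbors are removed before any
    flagged endpoint, and the screen is iterated until stable, so an
    isolated spike is removed while the plausible weights around it
    survive.  A patient's lone record has no neighbor and is kept.
    """
    log = ExclusionLog()
    lo, hi = config.breland_cutoffs_kg
    kept = range_filter(cohort.weights, lo, hi, log=log, step=1)

    rlo, rhi = config.breland_ratio_bounds
    ordered = kept.sort_values(["patient_id", "day_offset", "record_id"], kind="stable")
    removed_ids = []
    for _, grp in ordered.groupby("patient_id", sort=False):
        if len(grp) < 2:
            continue
        removed_ids.extend(
            _breland_patient(
                grp["weight_kg"].to_numpy(), grp["record_id"].to_numpy(), rlo, rhi
            )
        )
    out = kept["record_id"].isin(removed_ids)
    log.add(kept[out], "ratio_outlier", 2)
    return CleanResult.build("breland", kept[~out], log, config)


def _maciejewski_patient(
    weights: np.ndarray,
    record_ids: np.ndarray,
    window: int,
    floor_kg: float,
    fraction: float,
) -> np.ndarray:
    """Record ids removed by the rolling-SD rule for one patient (time order)."""
    vals = list(map(float, weights))
    rids = list(record_ids)
    removed = []
    while len(vals) >= window:
        flagged = None
        for s in range(len(vals) - window + 1):
            win = np.asarray(vals[s : s + window])
            sd = float(np.std(win, ddof=1))
            if sd > max(floor_kg, fraction * float(win.mean())):
                flagged = s
                break
        if flagged is None:
            break
        win = np.asarray(vals[flagged : flagged + window])
        med = float(np.median(win))
        # farthest from the window median; ties remove the larger weight
        local = max(range(window), key=lambda i: (abs(win[i] - med), win[i]))
        idx = flagged + local
        removed.append(rids[idx])
        del vals[idx], rids[idx]
    return np.asarray(removed)


def clean_maciejewski(
    cohort: Cohort, config: AllDataConfig = AllDataConfig()
) -> CleanResult:
    """Iterative rolling-window SD rule; the only all-data rule with no cutoffs.

    Per patient, consecutive-record windows are scanned in time order; the
    first window whose SD exceeds max(absolute floor, fraction of the window
    mean) has its record farthest from the window median removed, and the
    scan restarts, until no window is flagged or fewer records than the
    window size remain.  Short series pass through unchanged.
    """
    records = cohort.weights
    log = ExclusionLog()
    ordered = records.sort_values(
        ["patient_id", "day_offset", "record_id"], kind="stable"
    )
    removed_ids = []
    for _, grp in ordered.groupby("patient_id", sort=False):
        if len(grp) < config.maciejewski_window_size:
            continue
        removed = _maciejewski_patient(
            grp["weight_kg"].to_numpy(),
            grp["record_id"].to_numpy(),
            config.maciejewski_window_size,
            config.maciejewski_sd_floor_kg,
            config.maciejewski_sd_fraction,
        )
        removed_ids.extend(removed.tolist())
    out = records["record_id"].isin(removed_ids)
    log.add(records[out], "rolling_sd_outlier", 1)
    return CleanResult.build("maciejewski", records[~out], log, config)


def clean_littman(cohort: Cohort, config: AllDataConfig = AllDataConfig()) -> CleanResult:
    """Cutoffs then a CV-gated deviation rule.

    On cutoff survivors, each patient's mean and sample SD are computed
    once; only when the SD exceeds 10% of the mean (coefficient of
    variation gate) are records with |weight - mean| strictly greater than
    the SD removed.  No recomputation after removals; both inequalities
    strict, so a deviation exactly equal to the SD survives.
    """
    log = ExclusionLog()
    lo, hi = config.littman_cutoffs_kg
    kept = range_filter(cohort.weights, lo, hi, log=log, step=1)

    grp = kept.groupby("patient_id")["weight_kg"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # NaN for single-record patients
    gate = sd > config.littman_cv_threshold * mean
    out = gate.fillna(False) & ((kept["weight_kg"] - mean).abs() > sd)
    log.add(kept[out], "cv_outlier", 2)
    return CleanResult.build("littman", kept[~out], log, config)
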