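"""Synthetic longitudinal-vitals generator with labeled contamination.

No public deposit of VHA vitals exists, so every algorithm here is
exercised on generated data that emulates a large primary-care cohort's
published marginals: ~12 weight measurements per patient over a 4-year
window with a heavily overdispersed visit-count distribution, population
weight ~94 kg (SD 22), ~5% single-measurement patients, and three latent
trajectory classes (loss / maintain / gain) with linear class-mean slopes.

Contamination is injected with per-record truth labels — implausible
extremes (including exact 0 and 674 kg), pound-entered values, digit
typos, and same-day duplicates — so cleaning recall and specificity can be
measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import ContaminationRates, GeneratorConfig
from .records import Cohort, assemble_cohort
from .result import CleanResult

__all__ = [
    "SyntheticData",
    "generate_cohort",
    "inject_contamination",
    "evaluate_cleaning",
    "LB_PER_KG",
]

LB_PER_KG = 2.20462

CLASS_NAMES = ("loss", "maintain", "gain")


@dataclass
class SyntheticData:
    """Generated tables in the ingestion schema plus truth labels.

    ``vitals``: ``record_id, patient_id, facility_id, date, kind, raw_value``
    (height rows carry negative record ids so weight ids stay contiguous).
    ``truth_records``: per weight record, ``record_id, label,
    true_weight_kg`` where label is one of valid / extreme_value /
    unit_error / digit_typo / duplicate and the true weight is the
    uncorrupted value.  ``truth_patients``: per patient, trajectory class,
    true intercept and slope (kg per year).
    """

    vitals: pd.DataFrame
    cohort_table: pd.DataFrame
    truth_records: pd.DataFrame
    truth_patients: pd.DataFrame

    def assemble(self, collection_window_days=(-730, 730)) -> Cohort:
        return assemble_cohort(self.vitals, self.cohort_table, collection_window_days)

    def to_csv(self, directory: str) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        self.vitals.to_csv(os.path.join(directory, "vitals.csv"), index=False)
        self.cohort_table.to_csv(os.path.join(directory, "cohort.csv"), index=False)
        self.truth_records.to_csv(os.path.join(directory, "truth_records.csv"), index=False)
        self.truth_patients.to_csv(os.path.join(directory, "truth_patients.csv"), index=False)


def _draw_visit_counts(rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    """Overdispersed per-patient visit counts.

    Negative-binomial with the configured mean and SD; a configured
    fraction of patients is forced to a single measurement, the rest to at
    least two.
    """
    mu, var = cfg.visits_mean, cfg.visits_sd**2
    k = mu**2 / (var - mu)
    p = k / (k + mu)
    counts = rng.negative_binomial(k, p, size=cfg.n_patients)
    counts = np.maximum(counts, 2)
    singles = rng.random(cfg.n_patients) < cfg.single_measure_fraction
    counts[singles] = 1
    return counts


def _truncnorm(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _format_weight(value: float, rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    s = f"{value:.1f}"
    u = rng.random()
    if u < cfg.comma_decimal_fraction:
        return s.replace(".", ",")
    if u < cfg.comma_decimal_fraction + cfg.unit_suffix_fraction:
        return s + " kg"
    return s


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(), seed: int = 0
) -> SyntheticData:
    """Generate a labeled synthetic cohort; fully reproducible from `seed`.

    Per patient: a trajectory class, intercept and slope are drawn; visit
    days are uniform over the collection window; each weight is
    intercept + slope * (day / 365) + noise.  Contamination is then
    injected per ``config.contamination`` via :func:`inject_contamination`.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    n = cfg.n_patients
    lo, hi = cfg.collection_window_days

    classes = rng.choice(3, size=n, p=cfg.class_probs)
    intercepts = _truncnorm(
        rng, cfg.baseline_mean_kg, cfg.baseline_sd_kg, cfg.baseline_min_kg, np.inf, n
    )
    slopes = np.array(
        [
            rng.normal(cfg.class_slopes_kg_per_year[c], cfg.class_slope_sd[c])
            for c in classes
        ]
    )
    heights = _truncnorm(
        rng, cfg.height_mean_m, cfg.height_sd_m, *cfg.height_bounds_m, n
    ).round(2)
    facilities = rng.integers(0, cfg.n_facilities, size=n)
    counts = _draw_visit_counts(rng, cfg)

    year = cfg.index_year
    year_start = pd.Timestamp(year=year, month=1, day=1)
    index_days = rng.integers(0, 365, size=n)
    index_dates = year_start + pd.to_timedelta(index_days, unit="D")

    pids = np.repeat(np.arange(n), counts)
    days = rng.integers(lo, hi + 1, size=counts.sum())
    true_w = intercepts[pids] + slopes[pids] * days / 365.0
    if cfg.noise_sd_kg > 0:
        true_w = true_w + rng.normal(0, cfg.noise_sd_kg, size=len(days))
    true_w = np.maximum(np.round(true_w, 1), 0.1)

    weight_rows = pd.DataFrame(
        {
            "record_id": np.arange(len(pids)),
            "patient_id": [f"P{p:06d}" for p in pids],
            "facility_id": [f"F{facilities[p]:03d}" for p in pids],
            "date": (
                index_dates[pids] + pd.to_timedelta(days, unit="D")
            ).strftime("%Y-%m-%d"),
            "kind": "weight",
            "raw_value": [_format_weight(w, rng, cfg) for w in true_w],
        }
    )

    # height rows: 1-3 per patient, mostly repeats of the true value so a
    # clear mode exists, occasionally a discrepant remeasure
    n_heights = rng.choice([1, 2, 3], size=n, p=[0.6, 0.25, 0.15])
    h_pids = np.repeat(np.arange(n), n_heights)
    h_days = rng.integers(lo, hi + 1, size=n_heights.sum())
    h_vals = heights[h_pids].copy()
    discrepant = rng.random(len(h_vals)) < 0.2
    h_vals[discrepant] = np.round(
        h_vals[discrepant] + rng.choice([-0.02, 0.02], size=discrepant.sum()), 2
    )
    height_rows = pd.DataFrame(
        {
            "record_id": -np.arange(1, len(h_pids) + 1),
            "patient_id": [f"P{p:06d}" for p in h_pids],
            "facility_id": [f"F{facilities[p]:03d}" for p in h_pids],
            "date": (
                index_dates[h_pids] + pd.to_timedelta(h_days, unit="D")
            ).strftime("%Y-%m-%d"),
            "kind": "height",
            "raw_value": [f"{v:.2f}" for v in h_vals],
        }
    )

    vitals = pd.concat([weight_rows, height_rows], ignore_index=True)
    cohort_table = pd.DataFrame(
        {
            "patient_id": [f"P{p:06d}" for p in range(n)],
            "facility_id": [f"F{f:03d}" for f in facilities],
            "index_date": index_dates.strftime("%Y-%m-%d"),
        }
    )
    truth_records = pd.DataFrame(
        {
            "record_id": np.arange(len(pids)),
            "label": "valid",
            "true_weight_kg": true_w,
        }
    )
    truth_patients = pd.DataFrame(
        {
            "patient_id": [f"P{p:06d}" for p in range(n)],
            "trajectory_class": [CLASS_NAMES[c] for c in classes],
            "true_intercept_kg": intercepts,
            "true_slope_kg_per_year": slopes,
            "true_height_m": heights,
        }
    )
    data = SyntheticData(vitals, cohort_table, truth_records, truth_patients)
    contamination_seed = int(rng.integers(0, 2**31 - 1))
    return inject_contamination(data, cfg.contamination, seed=contamination_seed)


def _draw_extremes(
    rng: np.random.Generator, size: int, avoid: Optional[Tuple[float, float]]
) -> np.ndarray:
    """Implausible weight values in [0, 700] kg.

    A mixture spanning both tails — including exact 0 and 674 — plus a
    mid-range slab (227-340 kg) that sits inside the widest published
    cutoffs but outside the narrowest, so different algorithms disagree on
    it.  With `avoid` set, draws are resampled until they fall outside the
    given closed interval.
    """
    bands = rng.choice(6, size=size, p=[0.05, 0.05, 0.30, 0.10, 0.15, 0.35])
    vals = np.empty(size)
    vals[bands == 0] = 0.0
    vals[bands == 1] = 674.0
    vals[bands == 2] = rng.uniform(0.1, 23.0, (bands == 2).sum())
    vals[bands == 3] = rng.uniform(23.0, 36.0, (bands == 3).sum())
    vals[bands == 4] = rng.uniform(227.0, 340.0, (bands == 4).sum())
    vals[bands == 5] = rng.uniform(340.0, 700.0, (bands == 5).sum())
    if avoid is not None:
        lo, hi = avoid
        inside = (vals >= lo) & (vals <= hi)
        while inside.any():
            vals[inside] = np.where(
                rng.random(inside.sum()) < 0.5,
                rng.uniform(0.0, max(lo - 0.1, 0.0), inside.sum()),
                rng.uniform(hi + 0.1, 700.0, inside.sum()),
            )
            inside = (vals >= lo) & (vals <= hi)
    return np.round(vals, 1)


def _typo(value: float, rng: np.random.Generator) -> float:
    """Digit-entry error: shifted decimal or transposed leading digits."""
    mode = rng.integers(0, 3)
    if mode == 0:
        return round(value * 10.0, 1)
    if mode == 1:
        return round(value / 10.0, 2)
    digits = f"{value:.1f}".replace(".", "")
    if len(digits) >= 2:
        swapped = digits[1] + digits[0] + digits[2:]
        out = float(swapped) / 10.0
        return round(out, 1)
    return round(value * 10.0, 1)


def inject_contamination(
    data: SyntheticData,
    rates: ContaminationRates = ContaminationRates(),
    seed: int = 0,
) -> SyntheticData:
    """Corrupt a seeded random subset of weight records, updating labels.

    Each weight record is assigned at most one corruption; duplicates
    append a new same-day row with the same recorded value and carry the
    ``duplicate`` label themselves (the original row stays ``valid``).
    All rates zero returns the input unchanged.
    """
    rng = np.random.default_rng(seed)
    vitals = data.vitals.copy()
    truth = data.truth_records.copy()

    is_weight = vitals["kind"] == "weight"
    widx = vitals.index[is_weight].to_numpy()
    nW = len(widx)
    truth = truth.set_index("record_id")

    u = rng.random(nW)
    p1 = rates.extreme_value
    p2 = p1 + rates.unit_error
    p3 = p2 + rates.digit_typo
    p4 = p3 + rates.same_day_duplicate
    kind = np.full(nW, "valid", dtype=object)
    kind[u < p1] = "extreme_value"
    kind[(u >= p1) & (u < p2)] = "unit_error"
    kind[(u >= p2) & (u < p3)] = "digit_typo"
    kind[(u >= p3) & (u < p4)] = "duplicate"

    rec_ids = vitals.loc[widx, "record_id"].to_numpy()
    true_vals = truth.loc[rec_ids, "true_weight_kg"].to_numpy()

    ext = kind == "extreme_value"
    if ext.any():
        new_vals = _draw_extremes(rng, int(ext.sum()), rates.extreme_avoid_kg)
        vitals.loc[widx[ext], "raw_value"] = [f"{v:.1f}" for v in new_vals]
        truth.loc[rec_ids[ext], "label"] = "extreme_value"

    un = kind == "unit_error"
    if un.any():
        lb = np.round(true_vals[un] * LB_PER_KG, 1)
        vitals.loc[widx[un], "raw_value"] = [f"{v:.1f}" for v in lb]
        truth.loc[rec_ids[un], "label"] = "unit_error"

    ty = kind == "digit_typo"
    if ty.any():
        typos = [_typo(v, rng) for v in true_vals[ty]]
        vitals.loc[widx[ty], "raw_value"] = [f"{v:g}" for v in typos]
        truth.loc[rec_ids[ty], "label"] = "digit_typo"

    du = kind == "duplicate"
    if du.any():
        dup_rows = vitals.loc[widx[du]].copy()
        next_id = int(vitals["record_id"].max()) + 1
        dup_ids = np.arange(next_id, next_id + len(dup_rows))
        dup_rows["record_id"] = dup_ids
        vitals = pd.concat([vitals, dup_rows], ignore_index=True)
        dup_truth = pd.DataFrame(
            {"label": "duplicate", "true_weight_kg": true_vals[du]},
            index=pd.Index(dup_ids, name="record_id"),
        )
        truth = pd.concat([truth, dup_truth])

    return SyntheticData(
        vitals.reset_index(drop=True),
        data.cohort_table,
        truth.reset_index(),
        data.truth_patients,
    )


def evaluate_cleaning(clean_result: CleanResult, truth_records: pd.DataFrame) -> Dict:
    """Confusion summary of a record-level cleaning run against truth labels.

    Returns per-contamination-type recall (fraction of contaminated records
    the algorithm excluded) and overall specificity (fraction of valid
    records retained).  Aggregating algorithms have no record-level
    retained set — evaluate those at the patient level instead.
    """
    if clean_result.aggregated:
        raise ValueError(
            f"{clean_result.algorithm} aggregates records; record-level "
            "recall is undefined — evaluate at the patient/period level"
        )
    truth = truth_records.set_index("record_id")
    retained = set(clean_result.retained["record_id"])
    # records the algorithm never saw (dropped at ingestion) count as excluded
    labels = truth["label"]
    out: Dict[str, float] = {}
    for label in sorted(labels.unique()):
        ids = truth.index[labels == label]
        if label == "valid":
            out["specificity"] = float(np.mean([rid in retained for rid in ids]))
        else:
            out[f"recall_{label}"] = float(np.mean([rid not in retained for rid in ids]))
    n_bad = int((labels != "valid").sum())
    if n_bad:
        bad_ids = truth.index[labels != "valid"]
        out["recall_overall"] = float(np.mean([rid not in retained for rid in bad_ids]))
    out["n_contaminated"] = n_bad
    out["n_valid"] = int((labels == "valid").sum())
    return out
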