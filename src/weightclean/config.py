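"""Configuration objects for every tunable the cleaning algorithms expose.

All weight bounds are in kilograms, all windows and offsets in whole days,
all heights in meters.  Each cleaning function receives one of these
dataclasses and embeds a snapshot of it in its :class:`~weightclean.result.CleanResult`
so that any cleaned output can be traced back to the exact rule parameters
that produced it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml

__all__ = [
    "AllDataConfig",
    "PeriodConfig",
    "ContaminationRates",
    "GeneratorConfig",
    "CleaningConfigs",
    "load_configs",
]


def _check_bounds(name: str, bounds: Tuple[float, float]) -> None:
    low, high = bounds
    if not low < high:
        raise ValueError(f"{name}: lower bound {low} must be < upper bound {high}")


@dataclass(frozen=True)
class AllDataConfig:
    """Tunables for the six algorithms that use all weight measures.

    Defaults are the published cutoffs where the source printed them and a
    documented reconstruction where it did not (Breland's ratio bounds,
    Maciejewski's rolling-SD rule).
    """

    #: BMI plausibility band; records with BMI < low or > high are removed.
    buta_bmi_bounds: Tuple[float, float] = (11.0, 70.0)
    #: weight cutoffs, kg; records < low or > high removed (boundaries kept).
    chan_cutoffs_kg: Tuple[float, float] = (23.0, 340.0)
    #: within-patient SD multiplier for the deviation-from-mean rule.
    chan_sd_multiplier: float = 3.0
    #: "patient" computes mean/SD within patient; "cohort" across all records.
    chan_sd_scope: str = "patient"
    maguen_cutoffs_kg: Tuple[float, float] = (32.0, 318.0)
    #: records with |conditional residual| >= this (kg) are removed.
    maguen_residual_threshold_kg: float = 10.0
    #: "mixed" = random-intercept/slope model; "ols" = per-patient lines.
    maguen_trend_method: str = "mixed"
    breland_cutoffs_kg: Tuple[float, float] = (34.0, 318.0)
    #: closed bounds on the ratio of a weight to its temporal neighbors.
    breland_ratio_bounds: Tuple[float, float] = (2.0 / 3.0, 3.0 / 2.0)
    #: number of consecutive records per rolling window.
    maciejewski_window_size: int = 5
    #: a window is flagged when its SD exceeds max(floor, fraction * mean).
    maciejewski_sd_floor_kg: float = 3.0
    maciejewski_sd_fraction: float = 0.10
    littman_cutoffs_kg: Tuple[float, float] = (34.0, 272.0)
    #: the deviation rule fires only when within-patient SD/mean exceeds this.
    littman_cv_threshold: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "buta_bmi_bounds",
            "chan_cutoffs_kg",
            "maguen_cutoffs_kg",
            "breland_cutoffs_kg",
            "breland_ratio_bounds",
            "littman_cutoffs_kg",
        ):
            _check_bounds(name, getattr(self, name))
        if self.chan_sd_multiplier <= 0 or self.maguen_residual_threshold_kg <= 0:
            raise ValueError("SD multiplier and residual threshold must be positive")
        if self.maciejewski_window_size < 2:
            raise ValueError("maciejewski_window_size must be >= 2")
        if self.chan_sd_scope not in ("patient", "cohort"):
            raise ValueError("chan_sd_scope must be 'patient' or 'cohort'")
        if self.maguen_trend_method not in ("mixed", "ols"):
            raise ValueError("maguen_trend_method must be 'mixed' or 'ols'")


@dataclass(frozen=True)
class PeriodConfig:
    """Tunables for the six period-specific algorithms.

    Anchors are day offsets from the patient index date: baseline, 6 months
    and 12 months by default.  All windows are closed intervals in days.
    """

    anchors_days: Tuple[int, ...] = (0, 182, 365)
    jackson_window_days: int = 90
    jackson_cutoffs_kg: Tuple[float, float] = (34.0, 318.0)
    goodrich_window_days: int = 30
    goodrich_cutoffs_kg: Tuple[float, float] = (36.0, 227.0)
    #: per-anchor half-windows (baseline, 6-month, 12-month).
    janney_window_days: Tuple[int, ...] = (30, 60, 60)
    janney_baseline_cutoffs_kg: Tuple[float, float] = (41.0, 272.0)
    #: minimum total measures per patient ("K chosen by researcher").
    rosenberger_min_measures: int = 2
    rosenberger_window_days: int = 30
    #: anchors every 6 months across the whole collection window when True;
    #: only `anchors_days` otherwise.
    rosenberger_full_window: bool = True
    rosenberger_spacing_days: int = 182
    kazerooni_window_days: int = 30
    #: maximum plausible between-period change, kg (Goodrich, Janney).
    change_cap_kg: float = 45.0
    #: weights <= low or >= high removed (inclusive exclusion).
    noel_cutoffs_kg: Tuple[float, float] = (32.0, 318.0)
    noel_min_per_quarter: int = 1
    #: month the fiscal year starts (10 = October, the VHA convention);
    #: set to 1 for calendar quarters.
    fiscal_year_start_month: int = 10

    def __post_init__(self) -> None:
        if list(self.anchors_days) != sorted(set(self.anchors_days)):
            raise ValueError("anchors_days must be strictly increasing")
        if len(self.janney_window_days) != len(self.anchors_days):
            raise ValueError("janney_window_days must match anchors_days in length")
        for name in ("jackson_cutoffs_kg", "goodrich_cutoffs_kg",
                     "janney_baseline_cutoffs_kg", "noel_cutoffs_kg"):
            _check_bounds(name, getattr(self, name))
        if self.rosenberger_min_measures < 1:
            raise ValueError("rosenberger_min_measures must be >= 1")
        if self.change_cap_kg <= 0:
            raise ValueError("change_cap_kg must be positive")
        if min(self.jackson_window_days, self.goodrich_window_days,
               self.rosenberger_window_days, self.kazerooni_window_days,
               *self.janney_window_days) < 0:
            raise ValueError("windows must be non-negative")
        if not 1 <= self.fiscal_year_start_month <= 12:
            raise ValueError("fiscal_year_start_month must be in 1..12")


@dataclass(frozen=True)
class ContaminationRates:
    """Per-record probabilities for each contamination type.

    Gross weight errors are rare in practice (well under 1% of vitals rows),
    so the defaults are kept small; tests that need heavier contamination
    raise the rates explicitly.
    """

    extreme_value: float = 0.002
    unit_error: float = 0.002
    digit_typo: float = 0.001
    same_day_duplicate: float = 0.004
    #: when set, extreme draws avoid this closed interval entirely, so every
    #: injected extreme is guaranteed to lie outside (low, high).
    extreme_avoid_kg: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "extreme_avoid_kg":
                continue
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must be a probability, got {v}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic longitudinal-vitals generator.

    Marginals target a large primary-care cohort: ~12 weights per patient
    over a 4-year collection window with a heavily overdispersed count
    distribution, population weight ~94 kg (SD 22), ~5% of patients with a
    single measurement, and three latent weight-trajectory classes
    (loss / maintain / gain) with linear class-mean slopes.
    """

    n_patients: int = 1000
    collection_window_days: Tuple[int, int] = (-730, 730)
    visits_mean: float = 12.2
    visits_sd: float = 24.9
    single_measure_fraction: float = 0.05
    baseline_mean_kg: float = 94.3
    baseline_sd_kg: float = 22.0
    baseline_min_kg: float = 35.0
    #: loss / maintain / gain class probabilities.
    class_probs: Tuple[float, float, float] = (0.15, 0.70, 0.15)
    #: class-mean slopes, kg per 365 days.
    class_slopes_kg_per_year: Tuple[float, float, float] = (-1.5, 0.0, 2.2)
    class_slope_sd: Tuple[float, float, float] = (1.0, 0.3, 1.0)
    noise_sd_kg: float = 1.5
    height_mean_m: float = 1.76
    height_sd_m: float = 0.07
    height_bounds_m: Tuple[float, float] = (1.45, 2.05)
    n_facilities: int = 10
    #: index dates drawn uniformly in this calendar year.
    index_year: int = 2016
    contamination: ContaminationRates = field(default_factory=ContaminationRates)
    #: fraction of raw weight strings rendered with a comma decimal separator
    #: or a trailing unit, to exercise the raw-value parser.
    comma_decimal_fraction: float = 0.01
    unit_suffix_fraction: float = 0.005

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if self.visits_sd**2 <= self.visits_mean:
            raise ValueError("visits_sd^2 must exceed visits_mean (overdispersion)")
        if not 0 <= self.single_measure_fraction <= 1:
            raise ValueError("single_measure_fraction must be a probability")
        if self.collection_window_days[0] >= self.collection_window_days[1]:
            raise ValueError("collection window must be a nonempty interval")
        if self.noise_sd_kg < 0 or self.baseline_sd_kg <= 0:
            raise ValueError("scale parameters must be positive")


@dataclass(frozen=True)
class CleaningConfigs:
    """Bundle of the all-data and period-specific configurations."""

    all_data: AllDataConfig = field(default_factory=AllDataConfig)
    period: PeriodConfig = field(default_factory=PeriodConfig)


def _tupleize(value):
    return tuple(value) if isinstance(value, list) else value


def load_configs(path: str) -> CleaningConfigs:
    """Read a YAML/JSON file with optional ``all_data`` and ``period`` maps."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    all_kw = {k: _tupleize(v) for k, v in (raw.get("all_data") or {}).items()}
    per_kw = {k: _tupleize(v) for k, v in (raw.get("period") or {}).items()}
    return CleaningConfigs(
        all_data=AllDataConfig(**all_kw), period=PeriodConfig(**per_kw)
    )
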