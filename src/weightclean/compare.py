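"""Comparison harness: run every algorithm, tabulate, bootstrap.

Twelve cleaning rules plus a ``raw`` pseudo-algorithm (no cleaning) are
registered by name.  :func:`descriptive_summary` reproduces the standard
comparison table — patients and measurements retained with retention
percentages against the raw reference, and moments of the retained weight
distribution.  :func:`bootstrap_dispersion` resamples patients with
replacement, reapplies every algorithm to each resample, and summarizes
the spread of the retained-weight mean and SD across replicates.
"""

from __future__ import annotations

from typing import Callable, Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import allmeasures, periods
from .config import CleaningConfigs
from .records import Cohort
from .result import CleanResult, ExclusionLog

__all__ = [
    "REGISTRY",
    "ALL_ALGORITHMS",
    "run_all_algorithms",
    "descriptive_summary",
    "bootstrap_dispersion",
    "resample_patients",
]


def _clean_raw(cohort: Cohort, configs: CleaningConfigs) -> CleanResult:
    """The no-cleaning reference: everything retained."""
    return CleanResult.build("raw", cohort.weights, ExclusionLog(), None)


REGISTRY: Dict[str, Callable[[Cohort, CleaningConfigs], CleanResult]] = {
    "raw": _clean_raw,
    "buta": lambda c, cfg: allmeasures.clean_buta(c, cfg.all_data),
    "chan_raffa": lambda c, cfg: allmeasures.clean_chan_raffa(c, cfg.all_data),
    "maguen": lambda c, cfg: allmeasures.clean_maguen(c, cfg.all_data),
    "breland": lambda c, cfg: allmeasures.clean_breland(c, cfg.all_data),
    "maciejewski": lambda c, cfg: allmeasures.clean_maciejewski(c, cfg.all_data),
    "littman": lambda c, cfg: allmeasures.clean_littman(c, cfg.all_data),
    "rosenberger": lambda c, cfg: periods.clean_rosenberger(c, cfg.period),
    "noel": lambda c, cfg: periods.clean_noel(c, cfg.period),
    "kazerooni_lim": lambda c, cfg: periods.clean_kazerooni_lim(c, cfg.period),
    "jackson": lambda c, cfg: periods.clean_jackson(c, cfg.period),
    "goodrich": lambda c, cfg: periods.clean_goodrich(c, cfg.period),
    "janney": lambda c, cfg: periods.clean_janney(c, cfg.period),
}

#: the twelve cleaning rules, without the raw reference.
ALL_ALGORITHMS = tuple(name for name in REGISTRY if name != "raw")


def run_all_algorithms(
    cohort: Cohort,
    configs: Optional[CleaningConfigs] = None,
    names: Optional[Sequence[str]] = None,
) -> Dict[str, CleanResult]:
    """Apply each selected algorithm independently to the same cohort.

    The input is never mutated; each result carries its own exclusion
    ledger and config snapshot.  Unknown names raise with the valid list.
    """
    configs = configs or CleaningConfigs()
    if names is None:
        names = list(REGISTRY)
    unknown = [n for n in names if n not in REGISTRY]
    if unknown:
        raise ValueError(
            f"unknown algorithm(s) {unknown}; valid names: {sorted(REGISTRY)}"
        )
    return {name: REGISTRY[name](cohort, configs) for name in names}


def _weight_stats(values: pd.Series) -> Dict[str, float]:
    if len(values) == 0:
        return {k: float("nan") for k in
                ("mean", "sd", "median", "iqr", "min", "max")}
    q1, q3 = np.percentile(values, [25, 75])
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "median": float(values.median()),
        "iqr": float(q3 - q1),
        "min": float(values.min()),
        "max": float(values.max()),
    }


def descriptive_summary(
    cohort: Cohort, results: Dict[str, CleanResult]
) -> pd.DataFrame:
    """Retention counts and weight moments per algorithm, raw row first.

    Retention percentages are relative to the raw cohort (patients with at
    least one parsed weight; all parsed measurements).  For aggregating
    algorithms the measurement count is the number of raw measurements
    that contributed to an aggregate, while the moments are computed on
    the aggregate values themselves.
    """
    raw_patients = cohort.weights["patient_id"].nunique()
    raw_measures = len(cohort.weights)
    rows = []

    def add_row(name: str, res: Optional[CleanResult]) -> None:
        if res is None:  # raw reference
            n_pat, n_meas = raw_patients, raw_measures
            values = cohort.weights["weight_kg"]
        elif res.aggregated:
            n_pat = res.retained["patient_id"].nunique()
            n_meas = int(res.retained["n_contributing"].sum()) if len(res.retained) else 0
            values = res.retained["weight_kg"]
        else:
            n_pat = res.retained["patient_id"].nunique()
            n_meas = len(res.retained)
            values = res.retained["weight_kg"]
        rows.append(
            {
                "algorithm": name,
                "n_patients": n_pat,
                "pct_patients": 100.0 * n_pat / raw_patients if raw_patients else float("nan"),
                "n_measurements": n_meas,
                "pct_measurements": 100.0 * n_meas / raw_measures if raw_measures else float("nan"),
                **_weight_stats(values),
            }
        )

    add_row("raw", None)
    for name, res in results.items():
        if name == "raw":
            continue
        add_row(name, res)
    return pd.DataFrame(rows)


def resample_patients(
    cohort: Cohort, patient_ids: Sequence, rng: np.random.Generator, n_sample: int
) -> Cohort:
    """Draw `n_sample` patients with replacement into a new cohort.

    A patient drawn more than once contributes all their records each
    time; copies are relabeled (``pid#k``) so within-patient rules treat
    them as distinct patients, and record ids are reassigned to stay
    unique.
    """
    chosen = rng.choice(np.asarray(patient_ids, dtype=object), size=n_sample, replace=True)
    new_ids = [f"{pid}#{k}" for k, pid in enumerate(chosen)]

    patients = cohort.patients.set_index("patient_id").loc[chosen].reset_index()
    patients["patient_id"] = new_ids

    idx_map = cohort.weights.groupby("patient_id", sort=False).indices
    lens = np.array([len(idx_map.get(pid, ())) for pid in chosen])
    if lens.sum():
        rows = np.concatenate([idx_map[pid] for pid in chosen if pid in idx_map])
        weights = cohort.weights.iloc[rows].reset_index(drop=True)
        weights["patient_id"] = np.repeat(np.asarray(new_ids, dtype=object), lens)
        weights["record_id"] = np.arange(len(weights))
    else:
        weights = cohort.weights.iloc[0:0].copy()
    return Cohort(
        patients=patients,
        weights=weights,
        collection_window_days=cohort.collection_window_days,
    )


def bootstrap_dispersion(
    cohort: Cohort,
    configs: Optional[CleaningConfigs] = None,
    n_sample: int = 1000,
    n_reps: int = 100,
    seed: int = 0,
    algorithms: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Patient-level bootstrap of the retained-weight mean and SD.

    Each replicate draws `n_sample` patients with replacement (one shared
    resample per replicate, processed by every selected algorithm), cleans
    the resample, and records the mean and sample SD of retained weights.
    Returns one row per algorithm with the median and the empirical 80%
    and 95% quantile intervals (type-7 quantiles) of each statistic across
    replicates.
    """
    if cohort.n_patients < 1:
        raise ValueError("cohort must contain at least one patient")
    configs = configs or CleaningConfigs()
    if algorithms is None:
        algorithms = list(REGISTRY)
    rng = np.random.default_rng(seed)
    pids = cohort.weights["patient_id"].unique()

    stats: Dict[str, Dict[str, list]] = {
        a: {"mean": [], "sd": []} for a in algorithms
    }
    for _ in range(n_reps):
        sample = resample_patients(cohort, pids, rng, n_sample)
        results = run_all_algorithms(sample, configs, algorithms)
        for a, res in results.items():
            w = res.retained["weight_kg"]
            stats[a]["mean"].append(float(w.mean()) if len(w) else float("nan"))
            if len(w) > 1:
                stats[a]["sd"].append(float(w.std(ddof=1)))
            else:
                stats[a]["sd"].append(0.0 if len(w) == 1 else float("nan"))

    rows = []
    for a in algorithms:
        row = {"algorithm": a}
        for stat in ("mean", "sd"):
            vals = np.asarray(stats[a][stat])
            row[f"{stat}_median"] = float(np.nanmedian(vals))
            for lo, hi, tag in ((10, 90, "80"), (2.5, 97.5, "95")):
                ql, qh = np.nanpercentile(vals, [lo, hi])
                row[f"{stat}_q{tag}_low"] = float(ql)
                row[f"{stat}_q{tag}_high"] = float(qh)
        rows.append(row)
    return pd.DataFrame(rows)
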