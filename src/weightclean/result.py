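"""CleanResult: the common output contract of every cleaning algorithm.

A non-aggregating algorithm partitions its input records into ``retained``
and ``exclusions``; an aggregating algorithm (Jackson's window means, Noel's
quarterly medians) instead emits one row per patient-period, and records
that were folded into an aggregate appear in neither table.

Retained records keep the canonical weight-table columns
(``record_id, patient_id, facility_id, date, day_offset, weight_kg``);
aggregated outputs use ``patient_id, period, day_offset, weight_kg,
n_contributing, aggregation``, where ``day_offset`` is the anchor day (or
fiscal-quarter midpoint) the aggregate is attached to.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional

import pandas as pd

__all__ = ["CleanResult", "REASON_CODES", "ExclusionLog"]

#: fixed enumeration of exclusion reason codes.
REASON_CODES = frozenset(
    {
        "unparseable",
        "outside_collection_window",
        "below_cutoff",
        "above_cutoff",
        "too_few_measures",
        "bmi_out_of_range",
        "sd_outlier",
        "residual_outlier",
        "ratio_outlier",
        "rolling_sd_outlier",
        "cv_outlier",
        "outside_period_window",
        "not_selected_in_window",
        "missing_period",
        "too_few_in_quarter",
        "implausible_change",
    }
)

_EXCL_COLUMNS = ["record_id", "patient_id", "reason", "step"]

AGGREGATE_COLUMNS = [
    "patient_id",
    "period",
    "day_offset",
    "weight_kg",
    "n_contributing",
    "aggregation",
]


class ExclusionLog:
    """Accumulates per-record exclusions as an algorithm steps through rules."""

    def __init__(self) -> None:
        self._parts: List[pd.DataFrame] = []

    def add(self, records: pd.DataFrame, reason: str, step: int) -> None:
        if reason not in REASON_CODES:
            raise ValueError(f"unknown reason code: {reason!r}")
        if len(records) == 0:
            return
        part = records[["record_id", "patient_id"]].copy()
        part["reason"] = reason
        part["step"] = step
        self._parts.append(part)

    def frame(self) -> pd.DataFrame:
        if not self._parts:
            return pd.DataFrame(columns=_EXCL_COLUMNS)
        return pd.concat(self._parts, ignore_index=True)


def _config_snapshot(config: Any) -> Dict[str, Any]:
    if config is None:
        return {}
    if dataclasses.is_dataclass(config):
        return dataclasses.asdict(config)
    return dict(config)


@dataclass
class CleanResult:
    """Retained measurements plus the exclusion ledger of one algorithm run."""

    algorithm: str
    retained: pd.DataFrame
    exclusions: pd.DataFrame
    aggregated: bool = False
    config: Dict[str, Any] = field(default_factory=dict)
    #: non-fatal notes, e.g. {"trend_method": "ols_fallback"} or patients
    #: whose BMI step was skipped for lack of a derived height.
    flags: Dict[str, Any] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        algorithm: str,
        retained: pd.DataFrame,
        log: ExclusionLog,
        config: Any = None,
        aggregated: bool = False,
        flags: Optional[Dict[str, Any]] = None,
    ) -> "CleanResult":
        return cls(
            algorithm=algorithm,
            retained=retained.reset_index(drop=True),
            exclusions=log.frame(),
            aggregated=aggregated,
            config=_config_snapshot(config),
            flags=flags or {},
        )

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def retained_patients(self) -> pd.Index:
        return pd.Index(self.retained["patient_id"].unique())

    def to_csv(self, retained_path: str, exclusions_path: str) -> None:
        self.retained.to_csv(retained_path, index=False)
        self.exclusions.to_csv(exclusions_path, index=False)
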