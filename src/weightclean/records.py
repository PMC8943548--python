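"""Core data model: raw-value parsing, height derivation, BMI, cohort assembly.

Longitudinal vitals arrive as long-format delimited text, one row per
measurement (``patient_id, facility_id, date, kind, raw_value`` with an
optional ``record_id``), alongside a cohort table assigning each patient an
index date.  :func:`assemble_cohort` turns these into a :class:`Cohort`:
parsed weight records on a whole-day offset axis relative to each patient's
index date, one derived height per patient, and an ingestion ledger for
every row that could not be used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "parse_weight_value",
    "derive_patient_height",
    "compute_bmi",
    "assemble_cohort",
    "Cohort",
    "LB_TO_KG",
    "WEIGHT_COLUMNS",
]

LB_TO_KG = 0.45359237

#: canonical column order of the parsed weight table.
WEIGHT_COLUMNS = [
    "record_id",
    "patient_id",
    "facility_id",
    "date",
    "day_offset",
    "weight_kg",
]

VITALS_REQUIRED = ["patient_id", "facility_id", "date", "kind", "raw_value"]
COHORT_REQUIRED = ["patient_id", "facility_id", "index_date"]

_KEEP = set("0123456789.,+-")


def parse_weight_value(raw_value, unit_hint: str = "kg") -> Optional[float]:
    """Parse one raw measurement string into kilograms.

    All characters other than digits, decimal separators and signs are
    stripped; a single comma with no period is treated as a decimal point
    (European decimal notation).  Returns ``None`` when no digits remain or
    more than one decimal separator survives — parsing never raises.
    """
    if raw_value is None or (isinstance(raw_value, float) and np.isnan(raw_value)):
        return None
    s = "".join(ch for ch in str(raw_value) if ch in _KEEP)
    if not any(ch.isdigit() for ch in s):
        return None
    if s.count(",") == 1 and s.count(".") == 0:
        s = s.replace(",", ".")
    if s.count(".") + s.count(",") > 1:
        return None
    s = s.replace(",", ".")
    try:
        value = float(s)
    except ValueError:
        return None
    if unit_hint == "lb":
        value *= LB_TO_KG
    elif unit_hint != "kg":
        raise ValueError(f"unit_hint must be 'kg' or 'lb', got {unit_hint!r}")
    return value


def derive_patient_height(heights: pd.DataFrame) -> Optional[float]:
    """Collapse one patient's height records to a single height in meters.

    The modal value wins.  A patient with exactly two recorded values takes
    the later-dated one; modal ties with three or more records are broken
    toward the most recently recorded tied value.  Empty input -> ``None``.

    `heights` needs columns ``date`` and ``height_m``.
    """
    if len(heights) == 0:
        return None
    hs = heights.sort_values("date", kind="stable")
    values = hs["height_m"].to_numpy()
    if len(values) == 1:
        return float(values[0])
    if len(values) == 2:
        return float(values[-1]) if values[0] != values[1] else float(values[0])
    counts = hs["height_m"].value_counts()
    top = counts[counts == counts.max()].index
    if len(top) == 1:
        return float(top[0])
    # tie: most recent record among the tied values
    tied = hs[hs["height_m"].isin(top)]
    return float(tied["height_m"].iloc[-1])


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index: weight in kg divided by height in meters squared."""
    if not height_m > 0:
        raise ValueError(f"height must be positive, got {height_m}")
    return weight_kg / height_m**2


@dataclass
class Cohort:
    """A study cohort: patients with index dates, parsed weights, heights.

    ``patients`` columns: ``patient_id, facility_id, index_date, height_m,
    flag`` (``height_m`` is NaN when no height could be derived; ``flag`` is
    ``"no_weight_data"`` for patients without a parseable weight record).
    ``weights`` follows :data:`WEIGHT_COLUMNS`; ``day_offset`` is the whole
    number of days from the patient's index date.
    """

    patients: pd.DataFrame
    weights: pd.DataFrame
    collection_window_days: Tuple[int, int] = (-730, 730)
    #: rows dropped at ingestion, with reasons.
    ingest_exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["record_id", "patient_id", "reason", "step"]
        )
    )

    def __post_init__(self) -> None:
        known = set(self.patients["patient_id"])
        orphans = set(self.weights["patient_id"]) - known
        if orphans:
            raise ValueError(f"weights reference unknown patients: {sorted(orphans)[:5]}")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patients_with_weights(self) -> pd.Index:
        return pd.Index(self.weights["patient_id"].unique())

    def heights_by_patient(self) -> Dict:
        return dict(
            zip(self.patients["patient_id"], self.patients["height_m"])
        )


def _require(df: pd.DataFrame, columns: Sequence[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{table} table is missing required column(s): {missing}")


def assemble_cohort(
    vitals: pd.DataFrame,
    cohort_table: pd.DataFrame,
    collection_window_days: Tuple[int, int] = (-730, 730),
    unit_hint: str = "kg",
) -> Cohort:
    """Parse a long-format vitals table into a :class:`Cohort`.

    Weight rows are parsed with :func:`parse_weight_value`; unparseable rows
    and rows whose day offset falls outside the collection window are logged
    with reasons, never silently dropped.  Height rows are parsed the same
    way (meters) and collapsed per patient with :func:`derive_patient_height`.
    Patients with no usable weight record stay in the patient list, flagged
    ``no_weight_data``.
    """
    _require(vitals, VITALS_REQUIRED, "vitals")
    _require(cohort_table, COHORT_REQUIRED, "cohort")
    lo, hi = collection_window_days

    vit = vitals.copy()
    if "record_id" not in vit.columns:
        vit["record_id"] = np.arange(len(vit))
    if vit["record_id"].duplicated().any():
        dupes = vit.loc[vit["record_id"].duplicated(), "record_id"].head().tolist()
        raise ValueError(f"duplicate record_id values: {dupes}")
    vit["date"] = pd.to_datetime(vit["date"])

    patients = cohort_table[COHORT_REQUIRED].drop_duplicates("patient_id").copy()
    patients["index_date"] = pd.to_datetime(patients["index_date"])
    index_by_patient = patients.set_index("patient_id")["index_date"]

    excl_parts = []

    weights_raw = vit[vit["kind"] == "weight"].copy()
    weights_raw["weight_kg"] = [
        parse_weight_value(v, unit_hint) for v in weights_raw["raw_value"]
    ]
    bad = weights_raw[weights_raw["weight_kg"].isna()]
    if len(bad):
        excl_parts.append(_ledger(bad, "unparseable"))
    weights = weights_raw.dropna(subset=["weight_kg"]).copy()

    unknown = weights[~weights["patient_id"].isin(index_by_patient.index)]
    if len(unknown):
        raise ValueError(
            "vitals reference patients absent from the cohort table: "
            f"{sorted(unknown['patient_id'].unique())[:5]}"
        )
    weights["day_offset"] = (
        weights["date"] - weights["patient_id"].map(index_by_patient)
    ).dt.days.astype(int)
    outside = weights[(weights["day_offset"] < lo) | (weights["day_offset"] > hi)]
    if len(outside):
        excl_parts.append(_ledger(outside, "outside_collection_window"))
    weights = weights[(weights["day_offset"] >= lo) & (weights["day_offset"] <= hi)]
    weights = weights[WEIGHT_COLUMNS].reset_index(drop=True)

    heights_raw = vit[vit["kind"] == "height"].copy()
    heights_raw["height_m"] = [
        parse_weight_value(v, "kg") for v in heights_raw["raw_value"]
    ]
    heights = heights_raw.dropna(subset=["height_m"])
    derived = {
        pid: derive_patient_height(grp)
        for pid, grp in heights.groupby("patient_id", sort=False)
    }
    patients["height_m"] = patients["patient_id"].map(derived).astype(float)

    has_weight = set(weights["patient_id"])
    patients["flag"] = np.where(
        patients["patient_id"].isin(has_weight), "", "no_weight_data"
    )

    ingest = (
        pd.concat(excl_parts, ignore_index=True)
        if excl_parts
        else pd.DataFrame(columns=["record_id", "patient_id", "reason", "step"])
    )
    return Cohort(
        patients=patients.reset_index(drop=True),
        weights=weights,
        collection_window_days=(lo, hi),
        ingest_exclusions=ingest,
    )


def _ledger(rows: pd.DataFrame, reason: str) -> pd.DataFrame:
    part = rows[["record_id", "patient_id"]].copy()
    part["reason"] = reason
    part["step"] = 0
    return part
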