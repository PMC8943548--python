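"""Shared fixtures: hand-built cohorts and randomized mini-cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from weightclean.records import Cohort, WEIGHT_COLUMNS

INDEX_DATE = pd.Timestamp("2016-06-15")


def build_cohort(
    entries,
    heights=None,
    window=(-730, 730),
    facility_by_patient=None,
):
    """Build a Cohort from (patient_id, day_offset, weight_kg) triples.

    `heights` maps patient_id -> meters (NaN if absent).  Record ids are
    assigned in entry order; dates are index date + offset.
    """
    heights = heights or {}
    facility_by_patient = facility_by_patient or {}
    rows = []
    for rid, (pid, day, w) in enumerate(entries):
        rows.append(
            {
                "record_id": rid,
                "patient_id": pid,
                "facility_id": facility_by_patient.get(pid, "F0"),
                "date": INDEX_DATE + pd.Timedelta(days=int(day)),
                "day_offset": int(day),
                "weight_kg": float(w),
            }
        )
    pids = sorted({pid for pid, _, _ in entries})
    weights = (
        pd.DataFrame(rows, columns=WEIGHT_COLUMNS)
        if rows
        else pd.DataFrame(columns=WEIGHT_COLUMNS)
    )
    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "facility_id": [facility_by_patient.get(p, "F0") for p in pids],
            "index_date": INDEX_DATE,
            "height_m": [float(heights.get(p, np.nan)) for p in pids],
            "flag": "",
        }
    )
    return Cohort(patients=patients, weights=weights, collection_window_days=window)


def cohort_to_oracle_records(cohort: Cohort):
    """Record dicts in the shape the naive oracles expect."""
    return [
        {
            "record_id": int(r.record_id),
            "patient_id": r.patient_id,
            "day": int(r.day_offset),
            "weight": float(r.weight_kg),
            "date": r.date.date(),
        }
        for r in cohort.weights.itertuples()
    ]


def random_mini_cohort(rng: np.random.Generator, with_heights: bool = True):
    """A random cohort of <=10 patients x <=10 records for oracle checks.

    Weights mix a plausible bulk with occasional extremes (0-700 kg) and
    values parked near every cutoff boundary; days mix uniform scatter
    with clusters near the 0/182/365 anchors so period rules get hits.
    """
    n_pat = int(rng.integers(1, 11))
    entries = []
    heights = {}
    boundary_pool = np.array(
        [23.0, 32.0, 34.0, 36.0, 41.0, 227.0, 272.0, 318.0, 340.0]
    )
    for p in range(n_pat):
        pid = f"P{p}"
        heights[pid] = float(rng.uniform(1.45, 2.05)) if with_heights else np.nan
        n_rec = int(rng.integers(1, 11))
        base = rng.uniform(45, 180)
        for _ in range(n_rec):
            u = rng.random()
            if u < 0.60:
                w = base + rng.normal(0, 8)
            elif u < 0.75:
                w = rng.uniform(0, 700)
            elif u < 0.85:
                w = float(rng.choice(boundary_pool))
            else:
                w = base * float(rng.choice([0.5, 1.5, 2.2, 10.0, 0.1]))
            v = rng.random()
            if v < 0.5:
                day = int(rng.integers(-730, 731))
            else:
                anchor = int(rng.choice([0, 182, 365]))
                day = anchor + int(rng.integers(-100, 101))
            entries.append((pid, day, max(round(float(w), 1), 0.0)))
    return build_cohort(entries, heights=heights)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160323)


@pytest.fixture(scope="session")
def small_synthetic():
    """A 300-patient contaminated cohort shared by fast tests."""
    from weightclean import GeneratorConfig, generate_cohort

    data = generate_cohort(GeneratorConfig(n_patients=300), seed=7)
    return data, data.assemble()
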