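"""Naive, loop-based reference implementations of the 12 cleaning rules.

Deliberately unvectorized and independent of the package internals: plain
Python lists, the `statistics` module, and explicit loops.  Each function
takes records as a list of dicts with keys ``record_id, patient_id, day,
weight, date`` (date = datetime.date) plus rule parameters, and returns
the set of retained record ids (or, for the aggregating rules, a set of
(patient, period, value, n) tuples).
"""

from __future__ import annotations

import math
import statistics
from collections import defaultdict


def _by_patient(records):
    groups = defaultdict(list)
    for r in records:
        groups[r["patient_id"]].append(r)
    for recs in groups.values():
        recs.sort(key=lambda r: (r["day"], r["record_id"]))
    return groups


def _cutoff(records, lo, hi, inclusive_bounds_kept=True):
    kept = []
    for r in records:
        w = r["weight"]
        if inclusive_bounds_kept:
            if lo <= w <= hi:
                kept.append(r)
        else:
            if lo < w < hi:
                kept.append(r)
    return kept


def oracle_buta(records, heights, bmi_lo=11.0, bmi_hi=70.0):
    groups = _by_patient(records)
    kept = set()
    for pid, recs in groups.items():
        if len(recs) <= 1:
            continue
        h = heights.get(pid)
        for r in recs:
            if h is None or math.isnan(h):
                kept.add(r["record_id"])
                continue
            bmi = r["weight"] / h**2
            if bmi_lo <= bmi <= bmi_hi:
                kept.add(r["record_id"])
    return kept


def oracle_chan_raffa(records, lo=23.0, hi=340.0, k=3.0):
    surv = _cutoff(records, lo, hi)
    kept = set()
    for pid, recs in _by_patient(surv).items():
        ws = [r["weight"] for r in recs]
        if len(ws) < 3:
            kept.update(r["record_id"] for r in recs)
            continue
        m = statistics.mean(ws)
        sd = statistics.stdev(ws)
        for r in recs:
            if abs(r["weight"] - m) <= k * sd:
                kept.add(r["record_id"])
    return kept


def _ols_residuals_patient(recs):
    ts = [r["day"] / 365.0 for r in recs]
    ws = [r["weight"] for r in recs]
    tbar = sum(ts) / len(ts)
    wbar = sum(ws) / len(ws)
    sxx = sum((t - tbar) ** 2 for t in ts)
    sxy = sum((t - tbar) * (w - wbar) for t, w in zip(ts, ws))
    slope = sxy / sxx if sxx > 0 else 0.0
    return [w - (wbar + slope * (t - tbar)) for t, w in zip(ts, ws)]


def oracle_maguen_ols(records, lo=32.0, hi=318.0, threshold=10.0):
    surv = _cutoff(records, lo, hi)
    kept = set()
    for pid, recs in _by_patient(surv).items():
        for r, resid in zip(recs, _ols_residuals_patient(recs)):
            if abs(resid) < threshold:
                kept.add(r["record_id"])
    return kept


def _ratio_outside(w, neighbor, lo, hi):
    if neighbor == 0.0:
        return w != 0.0  # inf ratio is outside; 0/0 counts as inside
    r = w / neighbor
    return r < lo or r > hi


def oracle_breland(records, lo=34.0, hi=318.0, rlo=2.0 / 3.0, rhi=3.0 / 2.0):
    surv = _cutoff(records, lo, hi)
    kept = set()
    for pid, recs in _by_patient(surv).items():
        working = list(recs)
        while len(working) >= 2:
            n = len(working)
            flagged = []
            for i, r in enumerate(working):
                votes = []
                if i > 0:
                    votes.append(
                        _ratio_outside(r["weight"], working[i - 1]["weight"], rlo, rhi)
                    )
                if i < n - 1:
                    votes.append(
                        _ratio_outside(r["weight"], working[i + 1]["weight"], rlo, rhi)
                    )
                if votes and all(votes):
                    flagged.append(i)
            interior = [i for i in flagged if 0 < i < n - 1]
            drop = interior if interior else flagged
            if not drop:
                break
            for i in sorted(drop, reverse=True):
                del working[i]
        kept.update(r["record_id"] for r in working)
    return kept


def oracle_maciejewski(records, window=5, floor=3.0, fraction=0.10):
    kept = set()
    for pid, recs in _by_patient(records).items():
        working = list(recs)
        if len(working) < window:
            kept.update(r["record_id"] for r in working)
            continue
        while len(working) >= window:
            flagged = None
            for s in range(len(working) - window + 1):
                ws = [r["weight"] for r in working[s : s + window]]
                if statistics.stdev(ws) > max(floor, fraction * statistics.mean(ws)):
                    flagged = s
                    break
            if flagged is None:
                break
            ws = [r["weight"] for r in working[flagged : flagged + window]]
            med = statistics.median(ws)
            best = None
            for i in range(window):
                key = (abs(ws[i] - med), ws[i])
                if best is None or key > best[0]:
                    best = (key, flagged + i)
            del working[best[1]]
        kept.update(r["record_id"] for r in working)
    return kept


def oracle_littman(records, lo=34.0, hi=272.0, cv=0.10):
    surv = _cutoff(records, lo, hi)
    kept = set()
    for pid, recs in _by_patient(surv).items():
        ws = [r["weight"] for r in recs]
        if len(ws) < 2:
            kept.update(r["record_id"] for r in recs)
            continue
        m = statistics.mean(ws)
        sd = statistics.stdev(ws)
        if sd > cv * m:
            for r in recs:
                if abs(r["weight"] - m) <= sd:
                    kept.add(r["record_id"])
        else:
            kept.update(r["record_id"] for r in recs)
    return kept


def oracle_rosenberger(records, window_lo=-730, window_hi=730, k_min=2,
                       half_window=30, spacing=182):
    anchors = []
    a = 0
    while a >= window_lo:
        anchors.append(a)
        a -= spacing
    a = spacing
    while a <= window_hi:
        anchors.append(a)
        a += spacing
    kept = set()
    for pid, recs in _by_patient(records).items():
        if len(recs) < k_min:
            continue
        for r in recs:
            if any(abs(r["day"] - a) <= half_window for a in anchors):
                kept.add(r["record_id"])
    return kept


def _fiscal_quarter(date, start_month=10):
    months_since = (date.month - start_month) % 12
    q = months_since // 3 + 1
    fy = date.year + (1 if (start_month > 1 and date.month >= start_month) else 0)
    return f"FY{fy}Q{q}"


def oracle_noel(records, lo=32.0, hi=318.0, min_per_quarter=1, start_month=10):
    surv = _cutoff(records, lo, hi, inclusive_bounds_kept=False)
    cells = defaultdict(list)
    for r in surv:
        cells[(r["patient_id"], _fiscal_quarter(r["date"], start_month))].append(
            r["weight"]
        )
    out = set()
    for (pid, quarter), ws in cells.items():
        if len(ws) >= min_per_quarter:
            out.add((pid, quarter, round(statistics.median(ws), 6), len(ws)))
    return out


def oracle_kazerooni(records, anchors=(0, 182, 365), half_window=30):
    kept = set()
    for pid, recs in _by_patient(records).items():
        periods_hit = set()
        candidates = []
        for r in recs:
            for a in anchors:
                if abs(r["day"] - a) <= half_window:
                    periods_hit.add(a)
                    candidates.append(r)
                    break
        if periods_hit == set(anchors):
            kept.update(r["record_id"] for r in candidates)
    return kept


def oracle_jackson(records, lo=34.0, hi=318.0, anchors=(0, 182, 365), half_window=90):
    surv = _cutoff(records, lo, hi)
    out = set()
    for a in anchors:
        cells = defaultdict(list)
        for r in surv:
            if abs(r["day"] - a) <= half_window:
                cells[r["patient_id"]].append(r["weight"])
        for pid, ws in cells.items():
            out.add((pid, a, round(statistics.mean(ws), 6), len(ws)))
    return out


def _closest(recs, anchor):
    best = None
    for r in recs:
        key = (abs(r["day"] - anchor), r["day"], r["record_id"])
        if best is None or key < best[0]:
            best = (key, r)
    return best[1] if best else None


def oracle_goodrich(records, lo=36.0, hi=227.0, anchors=(0, 182, 365),
                    half_window=30, cap=45.0):
    surv = _cutoff(records, lo, hi)
    kept = set()
    for pid, recs in _by_patient(surv).items():
        selected = []
        for a in anchors:
            inwin = [r for r in recs if abs(r["day"] - a) <= half_window]
            c = _closest(inwin, a)
            if c is not None:
                selected.append(c)
        ok = True
        for prev, nxt in zip(selected, selected[1:]):
            if abs(nxt["weight"] - prev["weight"]) > cap:
                ok = False
        if ok:
            kept.update(r["record_id"] for r in selected)
    return kept


def oracle_janney(records, lo=41.0, hi=272.0, anchors=(0, 182, 365),
                  windows=(30, 60, 60), cap=45.0):
    surv = []
    for r in records:
        if abs(r["day"] - anchors[0]) <= windows[0] and not (lo <= r["weight"] <= hi):
            continue
        surv.append(r)
    kept = set()
    for pid, recs in _by_patient(surv).items():
        selected = []
        for a, w in zip(anchors, windows):
            inwin = [r for r in recs if abs(r["day"] - a) <= w]
            c = _closest(inwin, a)
            if c is not None:
                selected.append(c)
        seen = set()
        last = None
        for r in selected:
            if r["record_id"] in seen:
                continue
            if last is not None and abs(r["weight"] - last) > cap:
                continue
            seen.add(r["record_id"])
            kept.add(r["record_id"])
            last = r["weight"]
    return kept
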