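"""Shift-window hour accounting.

The analysis partitions each 07:00-anchored care-day into three fixed
provision windows — day ``[07:00, 14:00)`` (7 h), evening ``[14:00, 21:00)``
(7 h) and night ``[21:00, 07:00 next day)`` (10 h) — and charges infant
presence and clinical staff time to the windows they overlap. All intervals
are half-open ``[start, end)``, which makes the 24 h partition exact and
boundary charging unambiguous. The night window is attributed to the date it
starts, so hours between midnight and 06:59 belong to the previous date's
night shift. Arithmetic is carried in integer seconds internally; conversion
to hours happens at the edge.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SHIFT_TYPES = ("day", "evening", "night")
#: (start offset from the care-day's 07:00 anchor, duration), both in hours.
SHIFT_OFFSETS = {"day": (0, 7), "evening": (7, 7), "night": (14, 10)}
STAFF_CATEGORIES = ("RN", "RN_specialist", "nursing_assistant", "coordinator")
ACTIVITIES = ("clinical", "nonclinical")

_SECONDS_PER_HOUR = 3600


def care_day_of(ts: pd.Timestamp) -> pd.Timestamp:
    """Calendar date of the 07:00-anchored care-day containing ``ts``."""
    return (pd.Timestamp(ts) - pd.Timedelta(hours=7)).normalize()


def window_bounds(date: pd.Timestamp, shift_type: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    """[start, end) of one provision window attributed to ``date``."""
    off, dur = SHIFT_OFFSETS[shift_type]
    start = pd.Timestamp(date).normalize() + pd.Timedelta(hours=7 + off)
    return start, start + pd.Timedelta(hours=dur)


def build_windows(dates: Sequence | pd.DatetimeIndex, units: Iterable[str]) -> pd.DataFrame:
    """One row per (unit, date, shift type) provision window.

    ``weekend`` is keyed to the attributed date (the night starting Saturday
    21:00 is a weekend shift even though it ends on Monday-side 07:00... i.e.
    Sunday morning).
    """
    dates = pd.DatetimeIndex(pd.to_datetime(list(dates))).normalize()
    if len(dates) == 0:
        raise ValueError("empty date range")
    rows = []
    for unit in units:
        for date in dates:
            for shift_type in SHIFT_TYPES:
                start, end = window_bounds(date, shift_type)
                rows.append(
                    (
                        unit,
                        date,
                        shift_type,
                        start,
                        end,
                        SHIFT_OFFSETS[shift_type][1],
                        date.dayofweek >= 5,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "date", "shift_type", "start", "end", "duration_h", "weekend"],
    )


def windows_for_range(start_date, end_date, units: Iterable[str]) -> pd.DataFrame:
    """Windows for every attributed date in ``[start_date, end_date]``."""
    return build_windows(pd.date_range(start_date, end_date, freq="D"), units)


def overlap_seconds(start, end, wstart, wend) -> int:
    """Length in whole seconds of ``[start, end) ∩ [wstart, wend)``."""
    if end < start:
        raise ValueError(f"interval end {end} precedes start {start}")
    lo = max(pd.Timestamp(start), pd.Timestamp(wstart))
    hi = min(pd.Timestamp(end), pd.Timestamp(wend))
    if hi <= lo:
        return 0
    return int((hi - lo).total_seconds())


def overlap_hours(start, end, wstart, wend) -> float:
    """Overlap of two half-open intervals in hours (exact to 1 s)."""
    return overlap_seconds(start, end, wstart, wend) / _SECONDS_PER_HOUR


def subtract_intervals(
    interval: tuple[pd.Timestamp, pd.Timestamp],
    holes: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Remove ``holes`` (e.g. home-leave intervals) from a half-open interval."""
    pieces = [interval]
    for hs, he in sorted(holes):
        nxt = []
        for ps, pe in pieces:
            if he <= ps or hs >= pe:
                nxt.append((ps, pe))
                continue
            if hs > ps:
                nxt.append((ps, hs))
            if he < pe:
                nxt.append((he, pe))
        pieces = nxt
    return [(s, e) for s, e in pieces if e > s]


def merge_intervals(
    intervals: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Union of half-open intervals (overlapping or touching pieces coalesce)."""
    merged: list[list[pd.Timestamp]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _windows_by_day(windows: pd.DataFrame) -> dict:
    out: dict = {}
    for w in windows.itertuples(index=False):
        out.setdefault((w.unit_id, w.date), []).append(w)
    return out


def _iter_care_days(start: pd.Timestamp, end: pd.Timestamp):
    """Care-day dates whose [07:00, 07:00+24h) span intersects [start, end)."""
    d = care_day_of(start)
    last = care_day_of(end - pd.Timedelta(seconds=1))
    while d <= last:
        yield d
        d += pd.Timedelta(days=1)


def attribute_presence(
    admissions: pd.DataFrame,
    acuity: pd.DataFrame,
    windows: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Apportion infant presence to provision windows by acuity category.

    Presence is the admission interval minus any home-leave intervals. The
    category charged to a window is the acuity of the care-day the window
    belongs to, which automatically books early-morning (00:00–06:59) hours
    to the previous date's night shift.

    Returns
    -------
    (contrib, audit)
        ``contrib``: unit_id, date, shift_type, category, seconds.
        ``audit``: total presence seconds and seconds falling outside the
        supplied window set (nonzero when the windows do not span the cohort).
    """
    acuity = acuity.copy()
    acuity["care_day"] = pd.to_datetime(acuity["care_day"]).dt.normalize()
    cat = {
        (r.patient_id, r.care_day): r.category for r in acuity.itertuples(index=False)
    }
    wmap = _windows_by_day(windows)

    contrib: dict[tuple, int] = {}
    total_seconds = 0
    uncovered_seconds = 0
    for adm in admissions.itertuples(index=False):
        holes = getattr(adm, "home_leaves", None)
        if not isinstance(holes, (list, tuple)):
            holes = []
        for s, e in subtract_intervals((adm.admitted_at, adm.discharged_at), holes):
            total_seconds += int((e - s).total_seconds())
            for day in _iter_care_days(s, e):
                day_secs = 0
                day_windows = wmap.get((adm.unit_id, day), [])
                for w in day_windows:
                    secs = overlap_seconds(s, e, w.start, w.end)
                    if secs == 0:
                        continue
                    key = (adm.patient_id, day)
                    if key not in cat:
                        raise ValueError(
                            f"presence of patient {adm.patient_id} on care-day "
                            f"{day.date().isoformat()} has no acuity record"
                        )
                    k = (adm.unit_id, day, w.shift_type, cat[key])
                    contrib[k] = contrib.get(k, 0) + secs
                    day_secs += secs
                anchor = day + pd.Timedelta(hours=7)
                in_day = overlap_seconds(s, e, anchor, anchor + pd.Timedelta(hours=24))
                uncovered_seconds += in_day - day_secs

    out = pd.DataFrame(
        [(u, d, st, c, secs) for (u, d, st, c), secs in contrib.items()],
        columns=["unit_id", "date", "shift_type", "category", "seconds"],
    )
    audit = {"presence_seconds": total_seconds, "uncovered_seconds": uncovered_seconds}
    return out, audit


def _merge_staff_records(staffing: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Union overlapping records of the same person/unit/category/activity.

    Double-counting one person is never physically meaningful; overlaps are
    merged with a warning rather than rejected.
    """
    merged_rows = []
    n_merged = 0
    keys = ["person_id", "unit_id", "category", "activity"]
    for key, grp in staffing.groupby(keys, sort=False):
        intervals = list(zip(grp["start"], grp["end"]))
        agency = bool(grp["agency"].any())
        union = merge_intervals(intervals)
        if len(union) < len(intervals):
            n_merged += len(intervals) - len(union)
        for s, e in union:
            merged_rows.append((*key, s, e, agency))
    if n_merged:
        logger.warning("merged %d overlapping staff record(s)", n_merged)
    return (
        pd.DataFrame(merged_rows, columns=[*keys, "start", "end", "agency"]),
        n_merged,
    )


def build_ledgers(
    admissions: pd.DataFrame,
    acuity: pd.DataFrame,
    staffing: pd.DataFrame | None,
    windows: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """One ledger row per provision window.

    Infant hours are split by acuity category; staff hours are window-truncated
    *clinical* hours by staff category (nonclinical activity is excluded
    entirely, agency records count like employed staff). Coordinator hours are
    accumulated separately and never enter ``rn_hours``/``rn_spec_hours``.
    """
    contrib, audit = attribute_presence(admissions, acuity, windows)

    infant = {
        (r.unit_id, r.date, r.shift_type, r.category): r.seconds
        for r in contrib.itertuples(index=False)
    }

    staff: dict[tuple, int] = {}
    n_merged = 0
    if staffing is not None and len(staffing):
        bad_units = set(staffing["unit_id"]) - set(windows["unit_id"])
        if bad_units:
            raise ValueError(f"staff records reference unknown unit(s): {sorted(bad_units)}")
        bad_cat = set(staffing["category"]) - set(STAFF_CATEGORIES)
        if bad_cat:
            raise ValueError(f"unknown staff categor(ies): {sorted(bad_cat)}")
        durations = (staffing["end"] - staffing["start"]).dt.total_seconds()
        if (durations <= 0).any() or (durations > 24 * 3600).any():
            raise ValueError("staff record duration outside (0, 24] hours")

        clinical = staffing[staffing["activity"] == "clinical"]
        clinical, n_merged = _merge_staff_records(clinical)
        wmap = _windows_by_day(windows)
        for rec in clinical.itertuples(index=False):
            for day in _iter_care_days(rec.start, rec.end):
                for w in wmap.get((rec.unit_id, day), []):
                    secs = overlap_seconds(rec.start, rec.end, w.start, w.end)
                    if secs:
                        k = (rec.unit_id, day, w.shift_type, rec.category)
                        staff[k] = staff.get(k, 0) + secs

    rows = []
    for w in windows.itertuples(index=False):
        base = (w.unit_id, w.date, w.shift_type)
        coord = staff.get((*base, "coordinator"), 0)
        rows.append(
            (
                w.unit_id,
                w.date,
                w.shift_type,
                bool(w.weekend),
                float(w.duration_h),
                infant.get((*base, "IC"), 0) / _SECONDS_PER_HOUR,
                infant.get((*base, "HDC"), 0) / _SECONDS_PER_HOUR,
                infant.get((*base, "SC"), 0) / _SECONDS_PER_HOUR,
                staff.get((*base, "RN"), 0) / _SECONDS_PER_HOUR,
                staff.get((*base, "RN_specialist"), 0) / _SECONDS_PER_HOUR,
                staff.get((*base, "nursing_assistant"), 0) / _SECONDS_PER_HOUR,
                coord / _SECONDS_PER_HOUR,
                coord > 0,
            )
        )
    ledgers = pd.DataFrame(
        rows,
        columns=[
            "unit_id",
            "date",
            "shift_type",
            "weekend",
            "duration_h",
            "ic_hours",
            "hdc_hours",
            "sc_hours",
            "rn_hours",
            "rn_spec_hours",
            "na_hours",
            "coordinator_hours",
            "coordinator_present",
        ],
    )
    # sanity: infant hours can never exceed census ceiling
    cap = ledgers["duration_h"] * max(1, len(admissions))
    assert (ledgers[["ic_hours", "hdc_hours", "sc_hours"]].sum(axis=1) <= cap + 1e-9).all()
    report = {**audit, "merged_staff_records": n_merged, "n_windows": len(windows)}
    return ledgers, report
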