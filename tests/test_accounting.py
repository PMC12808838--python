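"""Window construction, interval overlap, presence and staff-hour attribution."""

import numpy as np
import pandas as pd
import pytest

from acuitybench.accounting import (
    build_ledgers,
    build_windows,
    care_day_of,
    overlap_hours,
    subtract_intervals,
    window_bounds,
    windows_for_range,
)
from conftest import acuity_frame, make_admission, staff_frame
from oracles import minute_infant_hours, minute_staff_hours

T = pd.Timestamp


def test_window_partition_and_counts():
    w = windows_for_range("2022-03-07", "2022-06-26", ["A", "B", "C"])
    assert len(w) == 3 * 112 * 3 == 1008
    one = w[(w.unit_id == "A") & (w.date == T("2022-03-07"))]
    assert sorted(one.duration_h) == [7, 7, 10]
    assert one.duration_h.sum() == 24
    # the three windows tile [07:00, 07:00+24h) exactly
    spans = sorted(zip(one.start, one.end))
    assert spans[0][0] == T("2022-03-07 07:00")
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 == s2
    assert spans[-1][1] == T("2022-03-08 07:00")


def test_weekend_flag_follows_attributed_date():
    w = build_windows([T("2022-03-12")], ["A"])  # a Saturday
    assert w.weekend.all()
    night = w[w.shift_type == "night"].iloc[0]
    assert night.start == T("2022-03-12 21:00") and night.end == T("2022-03-13 07:00")
    assert not build_windows([T("2022-03-11")], ["A"]).weekend.any()  # Friday


def test_care_day_anchor():
    assert care_day_of(T("2022-03-08 06:59")) == T("2022-03-07")
    assert care_day_of(T("2022-03-08 07:00")) == T("2022-03-08")


@pytest.mark.parametrize(
    "start, end, shift, expected",
    [
        ("2022-03-07 08:00", "2022-03-07 12:00", "day", 4.0),
        ("2022-03-07 06:30", "2022-03-07 15:30", "day", 7.0),
        ("2022-03-07 14:00", "2022-03-07 14:00", "day", 0.0),
        ("2022-03-07 13:30", "2022-03-07 14:00", "day", 0.5),
        ("2022-03-07 21:00", "2022-03-08 07:15", "night", 10.0),
        ("2022-03-08 00:00", "2022-03-08 06:59", "night", 419 / 60),
    ],
)
def test_overlap_hours_against_windows(start, end, shift, expected):
    ws, we = window_bounds(T("2022-03-07"), shift)
    assert overlap_hours(T(start), T(end), ws, we) == pytest.approx(expected, abs=1e-12)


def test_overlap_rejects_reversed_interval():
    ws, we = window_bounds(T("2022-03-07"), "day")
    with pytest.raises(ValueError, match="precedes"):
        overlap_hours(T("2022-03-07 12:00"), T("2022-03-07 08:00"), ws, we)


def test_subtract_intervals_home_leave():
    whole = (T("2022-03-07 10:00"), T("2022-03-10 10:00"))
    holes = [(T("2022-03-08 09:00"), T("2022-03-09 09:00"))]
    pieces = subtract_intervals(whole, holes)
    assert pieces == [
        (T("2022-03-07 10:00"), T("2022-03-08 09:00")),
        (T("2022-03-09 09:00"), T("2022-03-10 10:00")),
    ]


def _ledger_row(ledgers, date, shift):
    sel = ledgers[(ledgers.date == T(date)) & (ledgers.shift_type == shift)]
    assert len(sel) == 1
    return sel.iloc[0]


def test_early_morning_admission_charges_previous_nights_window():
    """Hours between 00:00 and 06:59 belong to the previous date's night shift."""
    admissions = pd.DataFrame(
        [make_admission("u1", "p1", "2022-03-08 03:00", "2022-03-08 09:00")]
    )
    acuity = acuity_frame([("p1", "2022-03-07", "IC"), ("p1", "2022-03-08", "IC")])
    windows = windows_for_range("2022-03-07", "2022-03-08", ["u1"])
    ledgers, _ = build_ledgers(admissions, acuity, None, windows)
    assert _ledger_row(ledgers, "2022-03-07", "night").ic_hours == 4.0
    assert _ledger_row(ledgers, "2022-03-08", "day").ic_hours == 2.0


def test_full_care_day_splits_7_7_10():
    admissions = pd.DataFrame(
        [make_admission("u1", "p1", "2022-03-07 07:00", "2022-03-08 07:00")]
    )
    acuity = acuity_frame([("p1", "2022-03-07", "HDC")])
    windows = windows_for_range("2022-03-07", "2022-03-07", ["u1"])
    ledgers, rep = build_ledgers(admissions, acuity, None, windows)
    assert ledgers.hdc_hours.tolist() == [7.0, 7.0, 10.0]
    assert rep["uncovered_seconds"] == 0


def test_discharge_on_boundary_charges_nothing_after():
    admissions = pd.DataFrame(
        [make_admission("u1", "p1", "2022-03-07 08:00", "2022-03-07 14:00")]
    )
    acuity = acuity_frame([("p1", "2022-03-07", "SC")])
    windows = windows_for_range("2022-03-07", "2022-03-07", ["u1"])
    ledgers, _ = build_ledgers(admissions, acuity, None, windows)
    assert _ledger_row(ledgers, "2022-03-07", "day").sc_hours == 6.0
    assert _ledger_row(ledgers, "2022-03-07", "evening").sc_hours == 0.0


def test_presence_without_acuity_is_an_error():
    admissions = pd.DataFrame(
        [make_admission("u1", "p1", "2022-03-07 08:00", "2022-03-09 08:00")]
    )
    acuity = acuity_frame([("p1", "2022-03-07", "SC")])
    windows = windows_for_range("2022-03-07", "2022-03-09", ["u1"])
    with pytest.raises(ValueError, match="no acuity record"):
        build_ledgers(admissions, acuity, None, windows)


def test_staff_hours_truncated_to_windows_and_categories():
    admissions = pd.DataFrame(
        [make_admission("u1", "p1", "2022-03-07 07:00", "2022-03-08 07:00")]
    )
    acuity = acuity_frame([("p1", "2022-03-07", "IC")])
    windows = windows_for_range("2022-03-07", "2022-03-07", ["u1"])
    staffing = staff_frame(
        [
            ("n1", "u1", "RN", "2022-03-07 07:00", "2022-03-07 21:00", "clinical", False),
            ("n2", "u1", "RN_specialist", "2022-03-07 06:30", "2022-03-07 15:30", "clinical", True),
            ("n3", "u1", "nursing_assistant", "2022-03-07 10:00", "2022-03-07 12:00", "nonclinical", False),
            ("c1", "u1", "coordinator", "2022-03-07 07:00", "2022-03-07 14:00", "clinical", False),
        ]
    )
    ledgers, _ = build_ledgers(admissions, acuity, staffing, windows)
    day = _ledger_row(ledgers, "2022-03-07", "day")
    evening = _ledger_row(ledgers, "2022-03-07", "evening")
    assert day.rn_hours == 7.0 and evening.rn_hours == 7.0
    assert day.rn_spec_hours == 7.0 and evening.rn_spec_hours == 1.5  # agency included
    assert day.na_hours == 0.0  # nonclinical excluded entirely
    assert day.coordinator_hours == 7.0 and day.coordinator_present
    assert not evening.coordinator_present


def test_overlapping_duplicate_staff_records_are_merged():
    admissions = pd.DataFrame(
        [make_admission("u1", "p1", "2022-03-07 07:00", "2022-03-08 07:00")]
    )
    acuity = acuity_frame([("p1", "2022-03-07", "SC")])
    windows = windows_for_range("2022-03-07", "2022-03-07", ["u1"])
    staffing = staff_frame(
        [
            ("n1", "u1", "RN", "2022-03-07 08:00", "2022-03-07 12:00", "clinical", False),
            ("n1", "u1", "RN", "2022-03-07 10:00", "2022-03-07 13:00", "clinical", False),
        ]
    )
    ledgers, rep = build_ledgers(admissions, acuity, staffing, windows)
    assert _ledger_row(ledgers, "2022-03-07", "day").rn_hours == 5.0
    assert rep["merged_staff_records"] == 1


def test_unknown_unit_and_bad_duration_rejected():
    admissions = pd.DataFrame(
        [make_admission("u1", "p1", "2022-03-07 07:00", "2022-03-08 07:00")]
    )
    acuity = acuity_frame([("p1", "2022-03-07", "SC")])
    windows = windows_for_range("2022-03-07", "2022-03-07", ["u1"])
    with pytest.raises(ValueError, match="unknown unit"):
        build_ledgers(
            admissions,
            acuity,
            staff_frame([("n1", "zz", "RN", "2022-03-07 08:00", "2022-03-07 12:00", "clinical", False)]),
            windows,
        )
    with pytest.raises(ValueError, match="duration"):
        build_ledgers(
            admissions,
            acuity,
            staff_frame([("n1", "u1", "RN", "2022-03-07 08:00", "2022-03-09 12:00", "clinical", False)]),
            windows,
        )


def _random_scenario(rng, base=T("2022-03-07")):
    """Small one-unit scenario with minute-resolution times over three dates."""
    def minute_in(lo_h, hi_h):
        return base + pd.Timedelta(minutes=int(rng.integers(lo_h * 60, hi_h * 60)))

    adm_rows, ac_rows = [], []
    for i in range(int(rng.integers(1, 5))):
        s = minute_in(0, 60)
        e = s + pd.Timedelta(minutes=int(rng.integers(60, 36 * 60)))
        leaves = []
        if rng.random() < 0.3:
            ls = s + (e - s) / 3
            leaves = [(ls.floor("min"), (ls + (e - s) / 4).floor("min"))]
        adm_rows.append(make_admission("u1", f"p{i}", s, e, leaves))
        d = care_day_of(s)
        while d <= care_day_of(e - pd.Timedelta(seconds=1)):
            ac_rows.append((f"p{i}", d, ["IC", "HDC", "SC"][rng.integers(3)]))
            d += pd.Timedelta(days=1)
    st_rows = []
    for j in range(int(rng.integers(0, 6))):
        s = minute_in(0, 60)
        e = s + pd.Timedelta(minutes=int(rng.integers(30, 14 * 60)))
        st_rows.append(
            (
                f"s{j}",
                "u1",
                ["RN", "RN_specialist", "nursing_assistant", "coordinator"][rng.integers(4)],
                s,
                e,
                ["clinical", "nonclinical"][rng.integers(2)],
                bool(rng.integers(2)),
            )
        )
    return (
        pd.DataFrame(adm_rows),
        acuity_frame(ac_rows),
        staff_frame(st_rows) if st_rows else None,
    )


def test_interval_arithmetic_matches_minute_oracle():
    """Randomized scenarios: ledger hours equal 1-minute brute-force accounting."""
    rng = np.random.default_rng(42)
    windows = windows_for_range("2022-03-06", "2022-03-09", ["u1"])
    for _ in range(25):
        admissions, acuity, staffing = _random_scenario(rng)
        ledgers, _ = build_ledgers(admissions, acuity, staffing, windows)
        oracle_inf = minute_infant_hours(admissions, acuity, windows)
        oracle_staff = minute_staff_hours(staffing, windows) if staffing is not None else {}
        col = {"IC": "ic_hours", "HDC": "hdc_hours", "SC": "sc_hours"}
        scol = {
            "RN": "rn_hours",
            "RN_specialist": "rn_spec_hours",
            "nursing_assistant": "na_hours",
            "coordinator": "coordinator_hours",
        }
        for row in ledgers.itertuples(index=False):
            for cat, c in col.items():
                expect = oracle_inf.get((row.unit_id, row.date, row.shift_type, cat), 0.0)
                assert abs(getattr(row, c) - expect) <= 1 / 60 + 1e-9
            for cat, c in scol.items():
                expect = oracle_staff.get((row.unit_id, row.date, row.shift_type, cat), 0.0)
                assert abs(getattr(row, c) - expect) <= 1 / 60 + 1e-9


def test_conservation_on_synthetic_cohort(small_run):
    """Sum of per-window infant-seconds equals total presence minus home leave."""
    b = small_run["bundle"]
    from acuitybench.accounting import attribute_presence, windows_for_range as wfr

    days = pd.to_datetime(small_run["acuity"]["care_day"])
    full = wfr(days.min(), days.max(), b.cohort_params.unit_ids)
    contrib, audit = attribute_presence(b.admissions, small_run["acuity"], full)
    assert audit["uncovered_seconds"] == 0
    assert int(contrib["seconds"].sum()) == audit["presence_seconds"]
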