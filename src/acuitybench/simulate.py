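"""Synthetic cohort and roster generator with known ground truth.

The study's hospital and register extracts are not public, so this module
emulates their statistical structure: admissions arrive per unit-week with
gestational-age strata and right-skewed lengths of stay matched to published
cohort moments; each admitted care-day carries an acuity category evolving as
a first-order Markov chain; daily intervention flags are then emitted as the
*minimal* flag set implying that category under the default adapted rule
table (plus non-qualifying noise flags), so classification round-trips
exactly. Rosters are generated backwards from the acuity-implied demand: per
provision window, clinical RN hours are laid down to hit a target provision
ratio to within one 0.25 h scheduling quantum, nursing assistants fill the
complement of the skill mix, and coordinator / nonclinical / agency records
are sprinkled in per their parameters. Every quantity a downstream stage
should recover is therefore known by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import accounting
from .accounting import SHIFT_OFFSETS, window_bounds
from .rules import load_ruleset, AcuityRuleSet

CATEGORIES = ("IC", "HDC", "SC")
GA_STRATA = ("23-28", "28-32", "32-37", ">37")
#: Scheduling quantum: real rosters are quarter-hour granular.
QUANTUM_H = 0.25

_NOISE_FLAGS = ("phototherapy", "tube_feeding", "antibiotics")


class ParameterError(ValueError):
    """Raised when generator parameters violate their invariants."""


def _check_probs(name: str, probs: Sequence[float]) -> None:
    arr = np.asarray(probs, dtype=float)
    if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
        raise ParameterError(f"{name} must be a probability vector summing to 1; got {probs}")


@dataclass
class CohortParams:
    """Cohort generator parameters.

    Defaults emulate a 16-week, three-unit neonatal service: gestational-age
    stratum proportions and per-stratum length-of-stay moments follow the
    published cohort table; the day-to-day acuity Markov chain and the
    per-unit acuity biases (tilting unit 0 toward intensive care and unit 2
    toward special care, mirroring level-4/3/2 case mixes) are invented
    plumbing with magnitudes chosen to reproduce the observed acuity mix.
    """

    n_units: int = 3
    n_weeks: int = 16
    start_date: str = "2022-03-07"
    admissions_per_week: float = 12.7
    ga_stratum_probs: tuple[float, ...] = (0.064, 0.082, 0.286, 0.568)
    los_mean_by_stratum: tuple[float, ...] = (52.6, 27.2, 9.5, 3.8)
    los_sd_by_stratum: tuple[float, ...] = (33.6, 18.6, 7.9, 3.9)
    #: Day-to-day acuity persistence: each day the category is kept with
    #: probability 0.75 and redrawn from the service-wide equilibrium mix
    #: (IC 0.17, HDC 0.41, SC 0.42) otherwise.
    acuity_transition: tuple[tuple[float, ...], ...] = (
        (0.7925, 0.1025, 0.1050),
        (0.0425, 0.8525, 0.1050),
        (0.0425, 0.1025, 0.8550),
    )
    initial_acuity_probs_by_stratum: tuple[tuple[float, ...], ...] = (
        (0.60, 0.35, 0.05),
        (0.35, 0.45, 0.20),
        (0.10, 0.45, 0.45),
        (0.05, 0.35, 0.60),
    )
    #: Per-unit multiplicative tilt on acuity probabilities (renormalized).
    unit_acuity_bias: tuple[tuple[float, ...], ...] = (
        (2.2, 1.3, 0.25),
        (1.0, 1.1, 0.95),
        (0.18, 1.0, 1.45),
    )
    #: HDC flag combinations: PN only / noninvasive only / PN+noninvasive /
    #: umbilical line only. The PN-only share drives the adapted-vs-original
    #: classification contrast.
    hdc_flag_probs: tuple[float, ...] = (0.18, 0.52, 0.18, 0.12)
    noise_flag_prob: float = 0.15
    home_leave_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_weeks < 1:
            raise ParameterError("n_weeks must be >= 1")
        if self.n_units < 1:
            raise ParameterError("n_units must be >= 1")
        if self.admissions_per_week < 0:
            raise ParameterError("admissions_per_week must be >= 0")
        _check_probs("ga_stratum_probs", self.ga_stratum_probs)
        _check_probs("hdc_flag_probs", self.hdc_flag_probs)
        for i, row in enumerate(self.acuity_transition):
            _check_probs(f"acuity_transition row {i}", row)
        for i, row in enumerate(self.initial_acuity_probs_by_stratum):
            _check_probs(f"initial_acuity_probs_by_stratum[{i}]", row)
        if len(self.initial_acuity_probs_by_stratum) != len(self.ga_stratum_probs):
            raise ParameterError("need one initial-acuity vector per GA stratum")
        if len(self.unit_acuity_bias) < self.n_units:
            raise ParameterError("need one acuity-bias vector per unit")
        for seq, nm in (
            (self.los_mean_by_stratum, "los_mean_by_stratum"),
            (self.los_sd_by_stratum, "los_sd_by_stratum"),
        ):
            if len(seq) != len(self.ga_stratum_probs) or any(x <= 0 for x in seq):
                raise ParameterError(f"{nm} must be strictly positive, one per stratum")
        if not 0 <= self.noise_flag_prob <= 1 or not 0 <= self.home_leave_prob <= 1:
            raise ParameterError("probabilities must lie in [0, 1]")

    @property
    def unit_ids(self) -> tuple[str, ...]:
        return tuple(f"unit{i + 1}" for i in range(self.n_units))

    @property
    def window_start(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_date)

    @property
    def window_dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.window_start, periods=self.n_weeks * 7, freq="D")


@dataclass
class RosterParams:
    """Roster generator parameters.

    ``target_ratio`` is the intended RN provision ratio per shift (optionally
    jittered by ``ratio_dispersion_sd``); ``skill_mix_rn_fraction`` the RN
    share of total nursing staff hours; ``specialist_share`` the specialist
    share of RN hours. Coordinator presence probabilities default to the
    observed day/evening/night pattern. Defaults for the mix parameters are
    the cohort's published medians.
    """

    target_ratio: float = 0.76
    ratio_dispersion_sd: float = 0.0
    skill_mix_rn_fraction: float = 0.465
    specialist_share: float = 0.73
    shift_length_range: tuple[float, float] = (4.0, 15.0)
    nonclinical_fraction: float = 0.05
    coordinator_day_prob: float = 0.854
    coordinator_evening_prob: float = 0.012
    coordinator_night_prob: float = 0.0
    agency_fraction: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.target_ratio <= 0:
            raise ParameterError("target_ratio must be > 0")
        if self.ratio_dispersion_sd < 0:
            raise ParameterError("ratio_dispersion_sd must be >= 0")
        for nm in (
            "skill_mix_rn_fraction",
            "specialist_share",
            "nonclinical_fraction",
            "coordinator_day_prob",
            "coordinator_evening_prob",
            "coordinator_night_prob",
            "agency_fraction",
        ):
            v = getattr(self, nm)
            if not 0 <= v <= 1:
                raise ParameterError(f"{nm} must lie in [0, 1]; got {v}")
        if self.skill_mix_rn_fraction == 0:
            raise ParameterError("skill_mix_rn_fraction must be > 0 (some RN hours needed)")
        lo, hi = self.shift_length_range
        if not (4.0 <= lo <= hi <= 15.0):
            raise ParameterError("shift_length_range must lie within [4, 15] hours")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline should recover."""

    acuity_by_infant_day: pd.DataFrame
    intended_ratio_by_shift: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["unit_id", "date", "shift_type", "intended_ratio"]
        )
    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _minute(ts: pd.Timestamp) -> pd.Timestamp:
    return ts.floor("min")


def _flags_for_category(category: str, rng: np.random.Generator, params: CohortParams) -> set[str]:
    """Minimal qualifying flag set for a target category, plus noise."""
    flags: set[str] = set()
    if category == "IC":
        flags.add("invasive_respiratory_support")
        if rng.random() < 0.5:
            flags.add("mechanical_respiratory_support")
        if rng.random() < 0.1:
            flags.add("chest_drain")
        if rng.random() < 0.3:
            flags.add("umbilical_line")
        if rng.random() < 0.5:
            flags.add("parenteral_nutrition")
    elif category == "HDC":
        combo = rng.choice(4, p=params.hdc_flag_probs)
        if combo == 0:
            flags.add("parenteral_nutrition")
        elif combo == 1:
            flags.add("noninvasive_respiratory_support")
        elif combo == 2:
            flags.update({"parenteral_nutrition", "noninvasive_respiratory_support"})
        else:
            flags.add("umbilical_line")
        if combo in (1, 2) and rng.random() < 0.15:
            flags.add("umbilical_line")
    if rng.random() < params.noise_flag_prob:
        flags.add(_NOISE_FLAGS[rng.integers(len(_NOISE_FLAGS))])
    return flags


def generate_cohort(
    params: CohortParams,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate admissions, daily intervention records and acuity ground truth.

    Admission timestamps fall inside the simulated window (stays may overhang
    the edges); every care-day of every stay gets exactly one intervention
    record consistent with its ground-truth category under the default
    adapted rule table. Identical parameters (including seed) give identical
    tables.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    vocab = tuple(load_ruleset(adapted=True).vocabulary)

    adm_rows, iv_rows, gt_rows = [], [], []
    counter = 0
    week_starts = [
        params.window_start + pd.Timedelta(days=7 * w) for w in range(params.n_weeks)
    ]
    for u_idx, unit in enumerate(params.unit_ids):
        bias = np.asarray(params.unit_acuity_bias[u_idx], dtype=float)
        init_by_stratum = [
            _tilt(np.asarray(p), bias) for p in params.initial_acuity_probs_by_stratum
        ]
        transition = np.stack(
            [_tilt(np.asarray(row), bias) for row in params.acuity_transition]
        )
        for wk_start in week_starts:
            n_adm = rng.poisson(params.admissions_per_week)
            offsets = np.sort(rng.uniform(0, 7 * 24 * 60, size=n_adm))
            for off in offsets:
                counter += 1
                pid = f"P{counter:05d}"
                admitted = _minute(wk_start + pd.Timedelta(minutes=float(off)))
                stratum = int(rng.choice(len(params.ga_stratum_probs), p=params.ga_stratum_probs))
                mu, sigma = _lognormal_params(
                    params.los_mean_by_stratum[stratum], params.los_sd_by_stratum[stratum]
                )
                los_days = max(1.0, float(rng.lognormal(mu, sigma)))
                discharged = _minute(admitted + pd.Timedelta(days=los_days))

                leaves: list[tuple[pd.Timestamp, pd.Timestamp]] = []
                if los_days >= 5 and rng.random() < params.home_leave_prob:
                    ls = admitted + pd.Timedelta(days=float(rng.uniform(1.5, los_days - 3.0)))
                    ld = float(rng.uniform(1.0, 2.0))
                    leaves.append((_minute(ls), _minute(ls + pd.Timedelta(days=ld))))

                adm_rows.append(
                    (unit, pid, admitted, discharged, GA_STRATA[stratum], leaves)
                )

                # acuity Markov path over the stay's 07:00-anchored care-days
                day = accounting.care_day_of(admitted)
                last = accounting.care_day_of(discharged - pd.Timedelta(seconds=1))
                state = int(rng.choice(3, p=init_by_stratum[stratum]))
                while day <= last:
                    category = CATEGORIES[state]
                    gt_rows.append((pid, day, category))
                    flags = _flags_for_category(category, rng, params)
                    iv_rows.append((pid, day, *[int(f in flags) for f in vocab]))
                    state = int(rng.choice(3, p=transition[state]))
                    day += pd.Timedelta(days=1)

    admissions = pd.DataFrame(
        adm_rows,
        columns=["unit_id", "patient_id", "admitted_at", "discharged_at", "ga_stratum", "home_leaves"],
    )
    interventions = pd.DataFrame(iv_rows, columns=["patient_id", "care_day", *vocab])
    truth = GroundTruth(
        acuity_by_infant_day=pd.DataFrame(
            gt_rows, columns=["patient_id", "care_day", "category"]
        )
    )
    return admissions, interventions, truth


def _tilt(probs: np.ndarray, bias: np.ndarray) -> np.ndarray:
    tilted = probs * bias
    return tilted / tilted.sum()


def _quantize_up(hours: float) -> float:
    return math.ceil(round(hours / QUANTUM_H, 9)) * QUANTUM_H


def _quantize_near(hours: float) -> float:
    return round(hours / QUANTUM_H) * QUANTUM_H


def _pack_records(hours: float, wstart: pd.Timestamp, duration: float) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Split a window's staff hours into full-window records plus one fill-in."""
    out = []
    remaining = hours
    while remaining >= duration - 1e-9:
        out.append((wstart, wstart + pd.Timedelta(hours=duration)))
        remaining -= duration
    if remaining > 1e-9:
        out.append((wstart, wstart + pd.Timedelta(hours=remaining)))
    return out


def generate_roster(
    params: RosterParams,
    demand: pd.DataFrame,
    windows: pd.DataFrame | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate staff shift records calibrated to acuity-implied demand.

    ``demand`` needs one row per provision window with columns ``unit_id``,
    ``date``, ``shift_type`` and ``recommended_rn_hours``. Per window, the
    clinical RN + specialist hours inside the window equal the (possibly
    jittered) target ratio times the recommendation, rounded *up* to the
    0.25 h quantum so a shift calibrated at 1.0 is never pushed under 1.0 by
    rounding alone. Returns ``(staffing, intended_ratio_by_shift)``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)

    if windows is not None:
        want = set(zip(windows["unit_id"], windows["date"], windows["shift_type"]))
        have = set(zip(demand["unit_id"], demand["date"], demand["shift_type"]))
        missing = want - have
        if missing:
            u, d, st = sorted(missing)[0]
            raise ValueError(
                f"demand table is missing {len(missing)} window(s), e.g. "
                f"{u} {pd.Timestamp(d).date().isoformat()} {st}"
            )

    coord_prob = {
        "day": params.coordinator_day_prob,
        "evening": params.coordinator_evening_prob,
        "night": params.coordinator_night_prob,
    }
    f_rn = params.skill_mix_rn_fraction
    rows, ratio_rows = [], []
    demand = demand.sort_values(["unit_id", "date", "shift_type"], kind="stable")
    for dem in demand.itertuples(index=False):
        wstart, _ = window_bounds(dem.date, dem.shift_type)
        duration = float(SHIFT_OFFSETS[dem.shift_type][1])
        rec = float(dem.recommended_rn_hours)
        stamp = f"{pd.Timestamp(dem.date):%Y%m%d}-{dem.shift_type[0]}"

        def emit(category: str, hours: float, slot_prefix: str) -> None:
            for i, (s, e) in enumerate(_pack_records(hours, wstart, duration)):
                rows.append(
                    (
                        f"{dem.unit_id}-{stamp}-{slot_prefix}{i:02d}",
                        dem.unit_id,
                        category,
                        s,
                        e,
                        "clinical",
                        bool(rng.random() < params.agency_fraction),
                    )
                )
                if rng.random() < params.nonclinical_fraction / max(1e-9, 1 - params.nonclinical_fraction):
                    ns = wstart + pd.Timedelta(hours=float(rng.integers(0, max(1, int((duration - 2) / QUANTUM_H))) * QUANTUM_H))
                    rows.append(
                        (
                            f"{dem.unit_id}-{stamp}-{slot_prefix}{i:02d}nc",
                            dem.unit_id,
                            category,
                            ns,
                            ns + pd.Timedelta(hours=2),
                            "nonclinical",
                            False,
                        )
                    )

        if rec > 0:
            r = params.target_ratio
            if params.ratio_dispersion_sd > 0:
                r = max(0.05, r + params.ratio_dispersion_sd * rng.standard_normal())
            provided = _quantize_up(r * rec)
            spec_hours = min(provided, _quantize_near(params.specialist_share * provided))
            rn_hours = provided - spec_hours
            na_hours = _quantize_near(provided * (1 - f_rn) / f_rn) if f_rn < 1 else 0.0
            emit("RN_specialist", spec_hours, "rs")
            emit("RN", rn_hours, "rn")
            emit("nursing_assistant", na_hours, "na")
            ratio_rows.append(
                (dem.unit_id, dem.date, dem.shift_type, provided / rec)
            )
        if rng.random() < coord_prob[dem.shift_type]:
            rows.append(
                (
                    f"{dem.unit_id}-{stamp}-co00",
                    dem.unit_id,
                    "coordinator",
                    wstart,
                    wstart + pd.Timedelta(hours=duration),
                    "clinical",
                    False,
                )
            )

    staffing = pd.DataFrame(
        rows,
        columns=["person_id", "unit_id", "category", "start", "end", "activity", "agency"],
    )
    intended = pd.DataFrame(
        ratio_rows, columns=["unit_id", "date", "shift_type", "intended_ratio"]
    )
    return staffing, intended


@dataclass
class Bundle:
    """A complete synthetic data set plus its generating parameters."""

    admissions: pd.DataFrame
    interventions: pd.DataFrame
    staffing: pd.DataFrame
    ground_truth: GroundTruth
    cohort_params: CohortParams
    roster_params: RosterParams


def simulate_bundle(
    cohort_params: CohortParams | None = None,
    roster_params: RosterParams | None = None,
    ruleset: AcuityRuleSet | None = None,
) -> Bundle:
    """Run the full generator: cohort, acuity-implied demand, calibrated roster."""
    from .benchmark import benchmark_table

    cohort_params = cohort_params or CohortParams()
    roster_params = roster_params or RosterParams()
    ruleset = ruleset or load_ruleset(adapted=True)

    admissions, interventions, truth = generate_cohort(cohort_params)
    windows = accounting.build_windows(cohort_params.window_dates, cohort_params.unit_ids)
    ledgers, _ = accounting.build_ledgers(
        admissions, truth.acuity_by_infant_day, None, windows
    )
    demand = benchmark_table(ledgers, ruleset.weights)[
        ["unit_id", "date", "shift_type", "recommended_rn_hours"]
    ]
    staffing, intended = generate_roster(roster_params, demand, windows=windows)
    truth.intended_ratio_by_shift = intended
    return Bundle(admissions, interventions, staffing, truth, cohort_params, roster_params)


def params_to_plain(obj) -> dict:
    """Dataclass params -> YAML-safe plain structure (tuples become lists)."""

    def conv(v):
        if isinstance(v, tuple):
            return [conv(x) for x in v]
        if isinstance(v, list):
            return [conv(x) for x in v]
        if isinstance(v, Mapping):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        return v

    return {k: conv(v) for k, v in asdict(obj).items()}
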