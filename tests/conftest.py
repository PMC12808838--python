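import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from acuitybench import (
    CohortParams,
    RosterParams,
    benchmark_table,
    build_windows,
    classify_cohort,
    load_ruleset,
    simulate_bundle,
)
from acuitybench.accounting import build_ledgers

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def adapted_rules():
    return load_ruleset(adapted=True)


@pytest.fixture(scope="session")
def original_rules():
    return load_ruleset(adapted=False)


@pytest.fixture(scope="session")
def small_bundle():
    """Three-week, three-unit synthetic bundle (default calibration, seed 7)."""
    return simulate_bundle(
        CohortParams(n_weeks=3, seed=7), RosterParams(target_ratio=0.76, seed=8)
    )


@pytest.fixture(scope="session")
def small_run(small_bundle, adapted_rules):
    """Classified, accounted and benchmarked view of the small bundle."""
    b = small_bundle
    acuity, cls_report = classify_cohort(b.interventions, adapted_rules, b.admissions)
    windows = build_windows(b.cohort_params.window_dates, b.cohort_params.unit_ids)
    ledgers, acc_report = build_ledgers(b.admissions, acuity, b.staffing, windows)
    bench = benchmark_table(ledgers, adapted_rules.weights)
    return {
        "bundle": b,
        "acuity": acuity,
        "cls_report": cls_report,
        "windows": windows,
        "ledgers": ledgers,
        "acc_report": acc_report,
        "bench": bench,
    }


def make_admission(unit, pid, start, end, leaves=()):
    return {
        "unit_id": unit,
        "patient_id": pid,
        "admitted_at": pd.Timestamp(start),
        "discharged_at": pd.Timestamp(end),
        "ga_stratum": ">37",
        "home_leaves": list(leaves),
    }


def acuity_frame(rows):
    """rows: (patient_id, care_day, category)"""
    return pd.DataFrame(
        [
            {
                "patient_id": p,
                "care_day": pd.Timestamp(d),
                "category": c,
                "matched_rule_id": "test",
            }
            for p, d, c in rows
        ]
    )


def staff_frame(rows):
    """rows: (person, unit, category, start, end, activity, agency)"""
    return pd.DataFrame(
        [
            {
                "person_id": p,
                "unit_id": u,
                "category": c,
                "start": pd.Timestamp(s),
                "end": pd.Timestamp(e),
                "activity": act,
                "agency": ag,
            }
            for p, u, c, s, e, act, ag in rows
        ]
    )
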