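"""CSV/YAML fixture I/O.

All timestamps are written as timezone-naive local time, ``YYYY-MM-DD HH:MM``
for instants and ``YYYY-MM-DD`` for care-day/shift dates. Home-leave
intervals are packed into one column as ``start/end`` pairs separated by
``;``. Floats are written with 6 significant digits. Writers are
deterministic: same frames, same bytes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .simulate import (
    Bundle,
    CohortParams,
    GroundTruth,
    RosterParams,
    params_to_plain,
    simulate_bundle,
)

SCHEMA_VERSION = "acuitybench-fixture/1"
FLOAT_FORMAT = "%.6g"
_TS = "%Y-%m-%d %H:%M"
_D = "%Y-%m-%d"

ADMISSIONS_FILE = "admissions.csv"
INTERVENTIONS_FILE = "interventions.csv"
STAFFING_FILE = "staffing.csv"
GT_ACUITY_FILE = "ground_truth_acuity.csv"
GT_RATIO_FILE = "ground_truth_ratio.csv"
MANIFEST_FILE = "manifest.yaml"


def _fmt_leaves(leaves) -> str:
    if not isinstance(leaves, (list, tuple)) or not leaves:
        return ""
    return ";".join(f"{s.strftime(_TS)}/{e.strftime(_TS)}" for s, e in leaves)


def _parse_leaves(text) -> list:
    if not isinstance(text, str) or not text.strip():
        return []
    out = []
    for piece in text.split(";"):
        s, e = piece.split("/")
        out.append((pd.Timestamp(s), pd.Timestamp(e)))
    return out


def frame_to_csv_text(df: pd.DataFrame, timestamp_cols=(), date_cols=()) -> str:
    df = df.copy()
    for c in timestamp_cols:
        df[c] = pd.to_datetime(df[c]).dt.strftime(_TS)
    for c in date_cols:
        df[c] = pd.to_datetime(df[c]).dt.strftime(_D)
    return df.to_csv(index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_csv(df: pd.DataFrame, path, timestamp_cols=(), date_cols=()) -> None:
    Path(path).write_text(frame_to_csv_text(df, timestamp_cols, date_cols))


def read_admissions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str, "patient_id": str})
    for c in ("admitted_at", "discharged_at"):
        df[c] = pd.to_datetime(df[c])
    if "home_leaves" in df.columns:
        df["home_leaves"] = df["home_leaves"].map(_parse_leaves)
    else:
        df["home_leaves"] = [[] for _ in range(len(df))]
    return df


def read_interventions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["care_day"] = pd.to_datetime(df["care_day"])
    return df


def read_staffing(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "unit_id": str, "category": str})
    for c in ("start", "end"):
        df[c] = pd.to_datetime(df[c])
    df["agency"] = df["agency"].astype(bool)
    return df


def read_acuity(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["care_day"] = pd.to_datetime(df["care_day"])
    return df


def read_ledgers(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str})
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_fixture(bundle: Bundle, directory) -> dict[str, Path]:
    """Write the three input tables, ground truth and a manifest.

    The target directory must already exist; all tables are serialized before
    the first byte is written, so validation failures leave no partial files.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {directory}")

    adm = bundle.admissions.copy()
    adm["home_leaves"] = adm["home_leaves"].map(_fmt_leaves)
    payload = {
        ADMISSIONS_FILE: frame_to_csv_text(
            adm, timestamp_cols=("admitted_at", "discharged_at")
        ),
        INTERVENTIONS_FILE: frame_to_csv_text(bundle.interventions, date_cols=("care_day",)),
        STAFFING_FILE: frame_to_csv_text(bundle.staffing, timestamp_cols=("start", "end")),
        GT_ACUITY_FILE: frame_to_csv_text(
            bundle.ground_truth.acuity_by_infant_day, date_cols=("care_day",)
        ),
        GT_RATIO_FILE: frame_to_csv_text(
            bundle.ground_truth.intended_ratio_by_shift, date_cols=("date",)
        ),
    }
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "cohort_params": params_to_plain(bundle.cohort_params),
        "roster_params": params_to_plain(bundle.roster_params),
        "date_range": {
            "start": bundle.cohort_params.window_dates[0].strftime(_D),
            "end": bundle.cohort_params.window_dates[-1].strftime(_D),
        },
        "row_counts": {name: text.count("\n") - 1 for name, text in payload.items()},
    }
    payload[MANIFEST_FILE] = yaml.safe_dump(manifest, sort_keys=True)

    paths = {}
    for name, text in payload.items():
        p = directory / name
        p.write_text(text)
        paths[name] = p
    return paths


def read_fixture(directory) -> Bundle:
    """Read a fixture directory back into in-memory tables."""
    directory = Path(directory)
    manifest = yaml.safe_load((directory / MANIFEST_FILE).read_text())
    cohort_params = CohortParams(
        **{
            k: _tuplify(v)
            for k, v in manifest["cohort_params"].items()
        }
    )
    roster_params = RosterParams(
        **{k: _tuplify(v) for k, v in manifest["roster_params"].items()}
    )
    truth = GroundTruth(
        acuity_by_infant_day=read_acuity(directory / GT_ACUITY_FILE),
        intended_ratio_by_shift=read_ledgers(directory / GT_RATIO_FILE)
        if (directory / GT_RATIO_FILE).exists()
        else GroundTruth(pd.DataFrame()).intended_ratio_by_shift,
    )
    return Bundle(
        admissions=read_admissions(directory / ADMISSIONS_FILE),
        interventions=read_interventions(directory / INTERVENTIONS_FILE),
        staffing=read_staffing(directory / STAFFING_FILE),
        ground_truth=truth,
        cohort_params=cohort_params,
        roster_params=roster_params,
    )


def simulate_from_manifest(manifest_path) -> Bundle:
    """Regenerate a bundle from a fixture manifest (same params, same seed)."""
    manifest = yaml.safe_load(Path(manifest_path).read_text())
    cohort = CohortParams(**{k: _tuplify(v) for k, v in manifest["cohort_params"].items()})
    roster = RosterParams(**{k: _tuplify(v) for k, v in manifest["roster_params"].items()})
    return simulate_bundle(cohort, roster)


def _tuplify(v):
    if isinstance(v, list):
        return tuple(_tuplify(x) for x in v)
    return v
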