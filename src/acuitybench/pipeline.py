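"""End-to-end pipeline: classify -> account -> benchmark -> summarize -> report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import accounting, io as abio
from .benchmark import BenchmarkSummary, benchmark_table, summarize_benchmark
from .rules import AcuityRuleSet, classify_cohort, load_ruleset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run over a fixture directory or files."""

    admissions_path: Path
    interventions_path: Path
    staffing_path: Path
    out_dir: Path
    rules_path: Path | None = None
    adapted: bool = True
    include_coordinator: bool = False
    start_date: str | None = None
    end_date: str | None = None
    missing_day_policy: str = "default_sc"

    @classmethod
    def for_fixture(cls, fixture_dir, out_dir, **kw) -> "RunConfig":
        fixture_dir = Path(fixture_dir)
        manifest = yaml.safe_load((fixture_dir / abio.MANIFEST_FILE).read_text())
        return cls(
            admissions_path=fixture_dir / abio.ADMISSIONS_FILE,
            interventions_path=fixture_dir / abio.INTERVENTIONS_FILE,
            staffing_path=fixture_dir / abio.STAFFING_FILE,
            out_dir=Path(out_dir),
            start_date=manifest["date_range"]["start"],
            end_date=manifest["date_range"]["end"],
            **kw,
        )

    def validate(self) -> None:
        for p in (self.admissions_path, self.interventions_path, self.staffing_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if self.rules_path is not None and not Path(self.rules_path).exists():
            raise FileNotFoundError(f"rule file not found: {self.rules_path}")


@dataclass
class RunResult:
    """In-memory results of a pipeline run."""

    acuity: pd.DataFrame
    ledgers: pd.DataFrame
    bench: pd.DataFrame
    summary: BenchmarkSummary
    report: dict


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    """Execute the full analysis and (optionally) write all stage outputs."""
    config.validate()
    ruleset = load_ruleset(config.rules_path, adapted=config.adapted)

    admissions = abio.read_admissions(config.admissions_path)
    interventions = abio.read_interventions(config.interventions_path)
    staffing = abio.read_staffing(config.staffing_path)
    logger.info(
        "read %d admissions, %d intervention days, %d staff records",
        len(admissions),
        len(interventions),
        len(staffing),
    )

    acuity, cls_report = classify_cohort(
        interventions, ruleset, admissions, config.missing_day_policy
    )

    if config.start_date and config.end_date:
        windows = accounting.windows_for_range(
            config.start_date, config.end_date, sorted(admissions["unit_id"].unique())
        )
    else:
        days = pd.to_datetime(acuity["care_day"])
        windows = accounting.windows_for_range(
            days.min(), days.max(), sorted(admissions["unit_id"].unique())
        )
    ledgers, acc_report = accounting.build_ledgers(admissions, acuity, staffing, windows)
    bench = benchmark_table(
        ledgers, ruleset.weights, include_coordinator=config.include_coordinator
    )
    summary = summarize_benchmark(bench)

    report = {
        "classification": cls_report,
        "accounting": acc_report,
        "headline": summary.headline,
        "config": {
            "adapted": config.adapted,
            "include_coordinator": config.include_coordinator,
            "rule_source_hash": ruleset.source_hash,
            "start_date": str(config.start_date),
            "end_date": str(config.end_date),
        },
    }

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        abio.write_csv(acuity, out / "acuity.csv", date_cols=("care_day",))
        abio.write_csv(ledgers, out / "ledgers.csv", date_cols=("date",))
        abio.write_csv(bench, out / "benchmark.csv", date_cols=("date",))
        abio.write_csv(
            pd.concat([summary.by_group, summary.skill_mix], ignore_index=True),
            out / "summaries.csv",
        )
        abio.write_csv(summary.tests_frame(), out / "tests.csv")
        manifest = {
            "config": report["config"],
            "counts": {
                "admissions": len(admissions),
                "care_days": cls_report["care_days"],
                "windows": int(acc_report["n_windows"]),
                "ratio_defined_shifts": summary.headline["n_ratio_defined"],
            },
            "input_hashes": {
                p.name: _sha256(p)
                for p in (
                    Path(config.admissions_path),
                    Path(config.interventions_path),
                    Path(config.staffing_path),
                )
            },
        }
        (out / "run_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
        (out / "report.txt").write_text(render_text_report(report))
    return RunResult(acuity=acuity, ledgers=ledgers, bench=bench, summary=summary, report=report)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def render_text_report(report: dict) -> str:
    h = report["headline"]
    lines = [
        "Acuity-adjusted RN staffing benchmark",
        "=" * 38,
        f"shift windows analysed:        {h['n_shifts']}",
        f"shifts with defined ratio:     {h['n_ratio_defined']}",
        f"fraction understaffed:         {100 * h['fraction_understaffed']:.1f}%",
        f"median RN provision ratio:     {h['ratio_median']:.2f} (IQR {h['ratio_iqr']:.2f})",
        f"ratio range:                   {h['ratio_min']:.2f} to {h['ratio_max']:.2f}",
        "",
        f"care-days classified:          {report['classification']['care_days']}",
        f"missing intervention days:     {report['classification']['missing_intervention_days']}",
        f"merged staff records:          {report['accounting']['merged_staff_records']}",
        "",
        "config: " + json.dumps(report["config"], sort_keys=True),
    ]
    return "\n".join(lines) + "\n"


def render_figures(
    bench: pd.DataFrame,
    ledgers: pd.DataFrame,
    acuity: pd.DataFrame,
    out_dir,
    fmt: str = "png",
) -> list[Path]:
    """Write the three standard figures.

    1. Boxplots of staff hours per shift by staff category and shift type
       (mild/extreme outliers marked by the boxplot convention).
    2. Daily census of admitted infants per acuity category.
    3. Histogram of the RN provision ratio with a reference line at 1.0.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if len(ledgers):
        fig, ax = plt.subplots(figsize=(8, 5))
        cats = [("rn_hours", "RN"), ("rn_spec_hours", "RN+"), ("na_hours", "NA")]
        data, labels = [], []
        for st in ("day", "evening", "night"):
            sub = ledgers[ledgers["shift_type"] == st]
            for col, lab in cats:
                data.append(sub[col].to_numpy())
                labels.append(f"{lab}\n{st}")
        ax.boxplot(data, tick_labels=labels, sym="o", flierprops={"markersize": 3})
        ax.set_ylabel("staff hours per shift")
        ax.set_title("Staff hours by category and shift type")
        p = out_dir / f"staff_hours_by_category.{fmt}"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        logger.warning("no ledger rows; skipping staff-hours figure")

    if len(acuity):
        census = (
            acuity.groupby(["care_day", "category"])["patient_id"]
            .nunique()
            .unstack(fill_value=0)
        )
        fig, ax = plt.subplots(figsize=(9, 4))
        for cat in ("IC", "HDC", "SC"):
            if cat in census:
                ax.plot(census.index, census[cat], label=cat)
        ax.set_ylabel("admitted infants")
        ax.set_title("Daily census per acuity category")
        ax.legend()
        p = out_dir / f"acuity_census.{fmt}"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        logger.warning("no acuity rows; skipping census figure")

    ratios = bench.loc[bench["ratio_defined"], "ratio"].dropna()
    if len(ratios):
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.hist(ratios, bins=30, edgecolor="black")
        ax.axvline(1.0, color="red", linestyle="--", label="recommended (1.0)")
        ax.set_xlabel("RN provision ratio")
        ax.set_ylabel("shifts")
        ax.set_title("RN provision ratio per shift")
        ax.legend()
        p = out_dir / f"provision_ratio_hist.{fmt}"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        logger.warning("no defined ratios; skipping histogram")
    return written
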