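"""RN provision-ratio benchmarking and shift-level summaries.

Recommended registered-nurse (RN) hours for a unit-shift follow the BAPM
infant-to-nurse ratios: each infant-hour is weighted 1.0 (intensive care,
1:1), 0.5 (high-dependency, 1:2) or 0.25 (special care, 1:4). The provision
ratio divides provided clinical RN hours (RN plus specialist RN; nursing
assistants excluded, coordinators optionally included) by the recommendation;
a ratio below 1.0 flags the shift as understaffed. Group contrasts use the
Kruskal–Wallis and Mann–Whitney U tests, both rank-based with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rules import DEFAULT_WEIGHTS

UNDERSTAFFED_THRESHOLD = 1.0


def recommended_rn_hours(infant_hours: Mapping[str, float], weights: Mapping[str, float] | None = None) -> float:
    """Acuity-weighted RN hours: sum of category hours times category weight."""
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    total = 0.0
    for cat, w in weights.items():
        h = float(infant_hours.get(cat, 0.0))
        if h < 0:
            raise ValueError(f"negative infant hours for {cat}: {h}")
        total += h * w
    return total


def provision_ratio(provided: float, recommended: float) -> tuple[float, bool]:
    """Ratio of provided to recommended RN hours and the understaffed flag.

    A zero recommendation has no clinical meaning as a denominator; the ratio
    comes back NaN and such rows are excluded from ratio summaries.
    """
    if provided < 0 or recommended < 0:
        raise ValueError("hours must be non-negative")
    if recommended == 0:
        return float("nan"), False
    ratio = provided / recommended
    return ratio, ratio < UNDERSTAFFED_THRESHOLD


def benchmark_table(
    ledgers: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
    include_coordinator: bool = False,
) -> pd.DataFrame:
    """Per unit-shift benchmark rows from hour ledgers.

    ``recommended_rn_count`` converts recommended hours to nurses by dividing
    by the window duration (7 h day/evening, 10 h night). Skill-mix columns:
    ``rn_fraction_of_staff`` is the (RN + specialist) share of all nursing
    staff hours; ``specialist_share`` the specialist share of RN hours.
    """
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    df = ledgers.copy()
    df["recommended_rn_hours"] = (
        df["ic_hours"] * weights["IC"]
        + df["hdc_hours"] * weights["HDC"]
        + df["sc_hours"] * weights["SC"]
    )
    df["recommended_rn_count"] = df["recommended_rn_hours"] / df["duration_h"]
    df["provided_rn_hours"] = df["rn_hours"] + df["rn_spec_hours"]
    if include_coordinator:
        df["provided_rn_hours"] += df["coordinator_hours"]
    df["ratio_defined"] = df["recommended_rn_hours"] > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ratio"] = np.where(
            df["ratio_defined"],
            df["provided_rn_hours"] / df["recommended_rn_hours"].replace(0, np.nan),
            np.nan,
        )
    df["understaffed"] = df["ratio_defined"] & (df["ratio"] < UNDERSTAFFED_THRESHOLD)

    staff_total = df["provided_rn_hours"] + df["na_hours"]
    rn_total = df["rn_hours"] + df["rn_spec_hours"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["rn_fraction_of_staff"] = np.where(
            staff_total > 0, rn_total / staff_total.replace(0, np.nan), np.nan
        )
        df["specialist_share"] = np.where(
            rn_total > 0, df["rn_spec_hours"] / rn_total.replace(0, np.nan), np.nan
        )
    cols = [
        "unit_id",
        "date",
        "shift_type",
        "weekend",
        "duration_h",
        "recommended_rn_hours",
        "recommended_rn_count",
        "provided_rn_hours",
        "ratio",
        "ratio_defined",
        "understaffed",
        "rn_fraction_of_staff",
        "specialist_share",
    ]
    return df[cols]


def _summary_row(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    n = len(values)
    mean = float(np.mean(values)) if n else float("nan")
    sd = float(np.std(values, ddof=1)) if n > 1 else float("nan")
    half = 1.96 * sd / np.sqrt(n) if n > 1 else float("nan")
    q1, med, q3 = (
        np.percentile(values, [25, 50, 75]) if n else (np.nan, np.nan, np.nan)
    )
    return {
        "n": n,
        "mean": mean,
        "sd": sd,
        "ci95_low": mean - half if n > 1 else float("nan"),
        "ci95_high": mean + half if n > 1 else float("nan"),
        "median": float(med),
        "iqr": float(q3 - q1),
        "min": float(np.min(values)) if n else float("nan"),
        "max": float(np.max(values)) if n else float("nan"),
    }


def summarize(
    df: pd.DataFrame,
    value_col: str,
    group_cols: Sequence[str] = (),
) -> pd.DataFrame:
    """Descriptive block per group: n, mean (SD, 95% CI), median (IQR), range.

    The 95% CI is the normal approximation mean ± 1.96·SD/√n; quantiles use
    linear interpolation, IQR = Q3 − Q1.
    """
    group_cols = list(group_cols)
    if not group_cols:
        row = _summary_row(df[value_col].to_numpy())
        return pd.DataFrame([{"variable": value_col, **row}])
    out = []
    for key, grp in df.groupby(group_cols, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        out.append(
            {**dict(zip(group_cols, key)), "variable": value_col, **_summary_row(grp[value_col].to_numpy())}
        )
    return pd.DataFrame(out)


@dataclass
class TestResult:
    """Outcome of one rank-based group comparison."""

    test_name: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method: str = "asymptotic"
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "groups": "|".join(self.groups),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": "|".join(str(n) for n in self.n_per_group),
            "method": self.method,
            "degenerate": self.degenerate,
        }


#: Exact (permutation) Kruskal–Wallis p-values up to this pooled size (no ties).
KW_EXACT_MAX_N = 10


def _kw_h_no_ties(ranks_by_group: Sequence[np.ndarray], n: int) -> float:
    h = 12.0 / (n * (n + 1)) * sum(r.sum() ** 2 / len(r) for r in ranks_by_group)
    return h - 3.0 * (n + 1)


def _kw_exact_p(sizes: Sequence[int], h_obs: float) -> float:
    """Permutation null of H over all group assignments of ranks 1..n."""
    import itertools

    n = sum(sizes)
    all_ranks = frozenset(range(1, n + 1))

    def rec(remaining: frozenset, sizes_left: Sequence[int], acc: list) -> tuple[int, int]:
        if len(sizes_left) == 1:
            groups = acc + [np.array(sorted(remaining), dtype=float)]
            h = _kw_h_no_ties(groups, n)
            return (1 if h >= h_obs - 1e-12 else 0), 1
        hits = total = 0
        for combo in itertools.combinations(sorted(remaining), sizes_left[0]):
            a, b = rec(
                remaining - frozenset(combo),
                sizes_left[1:],
                acc + [np.array(combo, dtype=float)],
            )
            hits += a
            total += b
        return hits, total

    hits, total = rec(all_ranks, list(sizes), [])
    return hits / total


def kruskal_wallis(samples: Sequence[Sequence[float]], labels: Sequence[str] | None = None) -> TestResult:
    """Kruskal–Wallis H test of identical distributions across k groups.

    The H statistic is rank-based with tie correction. The p-value comes
    from the exact permutation null when the pooled sample has at most
    ``KW_EXACT_MAX_N`` observations and no ties (the chi-square approximation
    is unreliable at such sizes); otherwise from the chi-square approximation
    with k−1 degrees of freedom. With every observation identical the
    statistic is degenerate (the tie correction divides by zero); reported
    as H = 0, p = 1 with a flag.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise ValueError("Kruskal–Wallis needs at least two groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    labels = tuple(labels) if labels is not None else tuple(f"g{i}" for i in range(len(samples)))
    ns = tuple(len(s) for s in samples)
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", labels, 0.0, 1.0, ns, "degenerate", True)
    stat, p = stats.kruskal(*samples)
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(pooled) <= KW_EXACT_MAX_N:
        return TestResult(
            "kruskal_wallis", labels, float(stat), _kw_exact_p(ns, float(stat)), ns, "exact"
        )
    return TestResult("kruskal_wallis", labels, float(stat), float(p), ns)


#: Exact Mann–Whitney p-values are used up to this smaller-group size (no ties).
MWU_EXACT_MAX_N = 8


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact null distribution when the smaller sample has at most
    ``MWU_EXACT_MAX_N`` observations and there are no ties; tie-corrected
    normal approximation (with continuity correction) otherwise. Identical
    constant samples are degenerate: U = n_a·n_b/2, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(
            "mann_whitney", labels, len(a) * len(b) / 2, 1.0, (len(a), len(b)), "degenerate", True
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and min(len(a), len(b)) <= MWU_EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        "mann_whitney", labels, float(res.statistic), float(res.pvalue), (len(a), len(b)), method
    )


def skill_mix_summary(
    bench: pd.DataFrame,
    group_cols: Sequence[str] = ("shift_type",),
) -> pd.DataFrame:
    """Summaries of per-shift skill-mix proportions.

    Proportions are computed per shift first (in :func:`benchmark_table`) and
    then summarized within groups; shifts with a zero denominator carry NaN
    and are excluded from the block (their count is the difference between
    the group size and ``n``).
    """
    blocks = []
    for col in ("rn_fraction_of_staff", "specialist_share"):
        blocks.append(summarize(bench, col, group_cols))
    return pd.concat(blocks, ignore_index=True)


@dataclass
class BenchmarkSummary:
    """Headline metrics plus grouped descriptive tables."""

    headline: dict
    by_group: pd.DataFrame
    skill_mix: pd.DataFrame
    tests: list[TestResult] = field(default_factory=list)

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.as_dict() for t in self.tests])


def summarize_benchmark(
    bench: pd.DataFrame,
    group_cols: Sequence[str] = ("unit_id", "shift_type", "weekend"),
    run_tests: bool = True,
) -> BenchmarkSummary:
    """Headline ratio metrics, Table-3-style group summaries and contrasts.

    Headline metrics (fraction understaffed, median/IQR/min/max ratio) are
    computed over ratio-defined shifts only. Contrasts: Kruskal–Wallis on the
    specialist share between shift types within each unit, and Mann–Whitney
    on the provision ratio weekday vs weekend per shift type (pooled across
    units and per unit).
    """
    defined = bench[bench["ratio_defined"]]
    n_def = len(defined)
    headline = {
        "n_shifts": int(len(bench)),
        "n_ratio_defined": int(n_def),
        "fraction_understaffed": float(defined["understaffed"].mean()) if n_def else float("nan"),
        **{
            f"ratio_{k}": v
            for k, v in _summary_row(defined["ratio"].to_numpy()).items()
            if k in ("median", "iqr", "min", "max", "mean", "sd")
        },
    }
    for unit, grp in bench.groupby("unit_id", sort=True):
        headline[f"recommended_rn_count_min_{unit}"] = float(grp["recommended_rn_count"].min())
        headline[f"recommended_rn_count_max_{unit}"] = float(grp["recommended_rn_count"].max())

    by_group = summarize(bench, "recommended_rn_count", group_cols)
    skill = skill_mix_summary(bench, ("unit_id", "shift_type"))

    tests: list[TestResult] = []
    if run_tests:
        for unit, grp in bench.groupby("unit_id", sort=True):
            samples, labels = [], []
            for st in ("day", "evening", "night"):
                vals = grp.loc[grp["shift_type"] == st, "specialist_share"].dropna()
                if len(vals):
                    samples.append(vals.to_numpy())
                    labels.append(f"{unit}:{st}")
            if len(samples) >= 2:
                tests.append(kruskal_wallis(samples, labels))
        for scope, sub in [("pooled", defined)] + [
            (str(u), g) for u, g in defined.groupby("unit_id", sort=True)
        ]:
            for st in ("day", "evening", "night"):
                wd = sub.loc[(sub["shift_type"] == st) & ~sub["weekend"], "ratio"].dropna()
                we = sub.loc[(sub["shift_type"] == st) & sub["weekend"], "ratio"].dropna()
                if len(wd) and len(we):
                    tests.append(
                        mann_whitney(
                            wd.to_numpy(),
                            we.to_numpy(),
                            (f"{scope}:{st}:weekday", f"{scope}:{st}:weekend"),
                        )
                    )
    return BenchmarkSummary(headline=headline, by_group=by_group, skill_mix=skill, tests=tests)
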