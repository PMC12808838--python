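"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's interval arithmetic and scipy's
p-value machinery: hour accounting is re-done minute by minute, and test
p-values by exhaustive enumeration of rank assignments.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def minute_infant_hours(admissions: pd.DataFrame, acuity: pd.DataFrame, windows: pd.DataFrame) -> dict:
    """Infant hours per (unit, date, shift, category) at 1-minute resolution."""
    cat = {
        (r.patient_id, pd.Timestamp(r.care_day).normalize()): r.category
        for r in acuity.itertuples(index=False)
    }
    out: dict = {}
    for w in windows.itertuples(index=False):
        minutes = pd.date_range(w.start, w.end - pd.Timedelta(minutes=1), freq="min")
        for adm in admissions.itertuples(index=False):
            if adm.unit_id != w.unit_id:
                continue
            holes = adm.home_leaves if isinstance(adm.home_leaves, (list, tuple)) else []
            count = 0
            for m in minutes:
                if not (adm.admitted_at <= m < adm.discharged_at):
                    continue
                if any(s <= m < e for s, e in holes):
                    continue
                count += 1
            if count:
                day = pd.Timestamp(w.date).normalize()
                key = (w.unit_id, day, w.shift_type, cat[(adm.patient_id, day)])
                out[key] = out.get(key, 0.0) + count / 60.0
    return out


def minute_staff_hours(staffing: pd.DataFrame, windows: pd.DataFrame) -> dict:
    """Clinical staff hours per (unit, date, shift, staff category), minute-wise."""
    out: dict = {}
    for w in windows.itertuples(index=False):
        minutes = pd.date_range(w.start, w.end - pd.Timedelta(minutes=1), freq="min")
        for rec in staffing.itertuples(index=False):
            if rec.unit_id != w.unit_id or rec.activity != "clinical":
                continue
            count = sum(1 for m in minutes if rec.start <= m < rec.end)
            if count:
                key = (w.unit_id, pd.Timestamp(w.date).normalize(), w.shift_type, rec.category)
                out[key] = out.get(key, 0.0) + count / 60.0
    return out


def mwu_exact_p(a, b) -> float:
    """Two-sided Mann–Whitney p by enumerating all C(n, n_a) allocations."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = rankdata(pooled)

    def u_of(idx) -> float:
        return ranks[list(idx)].sum() - na * (na + 1) / 2

    u_obs = u_of(range(na))
    us = np.array([u_of(c) for c in itertools.combinations(range(n), na)])
    p_le = (us <= u_obs + 1e-12).mean()
    p_ge = (us >= u_obs - 1e-12).mean()
    return min(1.0, 2 * min(p_le, p_ge))


def kw_permutation_p(groups) -> float:
    """Kruskal–Wallis permutation p: fraction of rank assignments with H >= H_obs."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)

    def h_of(parts) -> float:
        return 12.0 / (n * (n + 1)) * sum(
            r.sum() ** 2 / len(r) for r in parts
        ) - 3.0 * (n + 1)

    idx = 0
    obs_parts = []
    for s in sizes:
        obs_parts.append(ranks[idx : idx + s])
        idx += s
    h_obs = h_of(obs_parts)

    hits = total = 0
    for perm in itertools.permutations(range(n)):
        idx = 0
        parts = []
        for s in sizes:
            parts.append(ranks[list(perm[idx : idx + s])])
            idx += s
        hits += h_of(parts) >= h_obs - 1e-12
        total += 1
    return hits / total
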