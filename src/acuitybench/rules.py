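"""Rule-based daily acuity classification.

Each admitted infant care-day (a 24 h period anchored at 07:00 local time)
carries a set of boolean intervention flags taken from register daily reports
(mechanical/invasive/noninvasive respiratory support, umbilical lines, chest
drains, parenteral nutrition, ...). An ordered rule table maps the flag set to
one of three dependency categories:

* ``IC``  — intensive care, weighted 1.0 RN per infant (1:1)
* ``HDC`` — high-dependency care, weighted 0.5 (1:2)
* ``SC``  — special care, weighted 0.25 (1:4)

Rules are evaluated top-down, first match wins; a day matching no rule falls
to the default category (SC). The table ships as editable YAML data
(:data:`DEFAULT_RULES_PATH`); the ``adapted`` toggle selects how a day on
parenteral nutrition without any respiratory support is treated (HDC under the
adapted variant, IC under the original BAPM table).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CATEGORIES = ("IC", "HDC", "SC")
#: Ordering used for severity-monotonicity checks: higher is sicker.
SEVERITY = {"IC": 3, "HDC": 2, "SC": 1}
DEFAULT_WEIGHTS = {"IC": 1.0, "HDC": 0.5, "SC": 0.25}

DEFAULT_RULES_PATH = resources.files("acuitybench.data") / "default_rules.yaml"


class RuleConfigError(ValueError):
    """Raised when a rule document fails validation."""


@dataclass(frozen=True)
class Rule:
    """One classification predicate: all_of AND any_of AND none-of none_of."""

    rule_id: str
    category: str
    all_of: tuple[str, ...] = ()
    any_of: tuple[str, ...] = ()
    none_of: tuple[str, ...] = ()

    def matches(self, flags: frozenset[str] | set[str]) -> bool:
        if any(f not in flags for f in self.all_of):
            return False
        if self.any_of and not any(f in flags for f in self.any_of):
            return False
        if any(f in flags for f in self.none_of):
            return False
        return True


@dataclass
class AcuityRuleSet:
    """Validated, ordered rule table plus the per-category RN weights."""

    vocabulary: tuple[str, ...]
    rules: tuple[Rule, ...]
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    adapted: bool = True
    default_category: str = "SC"
    source_hash: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vocab = set(self.vocabulary)
        if len(vocab) != len(self.vocabulary):
            raise RuleConfigError("duplicate intervention names in vocabulary")
        for rule in self.rules:
            if rule.category not in CATEGORIES:
                raise RuleConfigError(
                    f"rule {rule.rule_id!r}: unknown category {rule.category!r}"
                )
            for flag in (*rule.all_of, *rule.any_of, *rule.none_of):
                if flag not in vocab:
                    raise RuleConfigError(
                        f"rule {rule.rule_id!r} references undeclared flag {flag!r}"
                    )
            if not (rule.all_of or rule.any_of):
                raise RuleConfigError(
                    f"rule {rule.rule_id!r} has no positive condition"
                )
        # severity-monotone ordering: IC rules before HDC rules before SC rules
        sev = [SEVERITY[r.category] for r in self.rules]
        if any(a < b for a, b in zip(sev, sev[1:])):
            bad = next(
                r.rule_id for r, a, b in zip(self.rules[1:], sev[1:], sev) if a > b
            )
            raise RuleConfigError(
                f"rule order is not severity-monotone at rule {bad!r}: "
                "all IC rules must precede HDC rules"
            )
        if self.default_category not in CATEGORIES:
            raise RuleConfigError(f"bad default category {self.default_category!r}")
        if set(self.weights) != set(CATEGORIES):
            raise RuleConfigError("weights must cover exactly IC, HDC, SC")
        w = self.weights
        if not (w["IC"] > w["HDC"] > w["SC"] > 0) or w["IC"] > 1:
            raise RuleConfigError(
                f"weights must be strictly decreasing IC > HDC > SC in (0, 1]; got {w}"
            )

    @property
    def qualifying_flags(self) -> frozenset[str]:
        """Flags that appear in some positive rule condition."""
        out: set[str] = set()
        for rule in self.rules:
            out.update(rule.all_of)
            out.update(rule.any_of)
        return frozenset(out)


def _parse_rule(entry: Mapping, adapted: bool) -> Rule:
    category = entry["category"]
    if isinstance(category, Mapping):
        category = category["adapted" if adapted else "original"]
    return Rule(
        rule_id=str(entry["id"]),
        category=str(category),
        all_of=tuple(entry.get("all_of", ())),
        any_of=tuple(entry.get("any_of", ())),
        none_of=tuple(entry.get("none_of", ())),
    )


def load_ruleset(source: str | Path | Mapping | None = None, adapted: bool = True) -> AcuityRuleSet:
    """Load and validate a rule table.

    Parameters
    ----------
    source
        Path to a YAML document, an already-parsed mapping, or ``None`` for
        the packaged default table.
    adapted
        Select the adapted variant (parenteral nutrition without respiratory
        support -> HDC) or the original one (-> IC). Rules whose ``category``
        is a ``{adapted: ..., original: ...}`` mapping are resolved here; all
        other rules are unchanged by the toggle.
    """
    source_hash = None
    if source is None:
        text = DEFAULT_RULES_PATH.read_text()
        doc = yaml.safe_load(text)
        source_hash = hashlib.sha256(text.encode()).hexdigest()
    elif isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text()
        doc = yaml.safe_load(text)
        source_hash = hashlib.sha256(text.encode()).hexdigest()

    try:
        vocabulary = tuple(doc["vocabulary"])
        rules = tuple(_parse_rule(entry, adapted) for entry in doc["rules"])
        weights = {str(k): float(v) for k, v in doc["weights"].items()}
    except (KeyError, TypeError) as exc:
        raise RuleConfigError(f"malformed rule document: {exc}") from exc

    return AcuityRuleSet(
        vocabulary=vocabulary,
        rules=rules,
        weights=weights,
        adapted=adapted,
        default_category=str(doc.get("default_category", "SC")),
        source_hash=source_hash,
    )


def classify_day(flags: Iterable[str], ruleset: AcuityRuleSet) -> tuple[str, str]:
    """Classify one care-day; returns ``(category, matched_rule_id)``.

    First matching rule wins; ``("SC", "default")`` when none matches.
    Unknown flag names are rejected.
    """
    flagset = frozenset(flags)
    unknown = flagset - set(ruleset.vocabulary)
    if unknown:
        raise RuleConfigError(f"unknown intervention flags: {sorted(unknown)}")
    for rule in ruleset.rules:
        if rule.matches(flagset):
            return rule.category, rule.rule_id
    return ruleset.default_category, "default"


def admitted_care_days(admissions: pd.DataFrame) -> pd.DataFrame:
    """Expand admissions into one row per admitted (patient, care-day).

    A care-day runs 07:00 -> 07:00; day ``d`` is admitted when
    ``[d 07:00, d+1 07:00)`` intersects the stay ``[admitted_at, discharged_at)``.
    """
    from .accounting import care_day_of  # local import to avoid a cycle

    rows = []
    for adm in admissions.itertuples(index=False):
        start = care_day_of(adm.admitted_at)
        end = care_day_of(adm.discharged_at - pd.Timedelta(seconds=1))
        for day in pd.date_range(start, end, freq="D"):
            rows.append((adm.patient_id, adm.unit_id, day.normalize()))
    return pd.DataFrame(rows, columns=["patient_id", "unit_id", "care_day"])


def classify_cohort(
    interventions: pd.DataFrame,
    ruleset: AcuityRuleSet,
    admissions: pd.DataFrame,
    missing_day_policy: str = "default_sc",
) -> tuple[pd.DataFrame, dict]:
    """Classify every admitted care-day of a cohort.

    Parameters
    ----------
    interventions
        One row per (patient_id, care_day) with one 0/1 column per
        intervention flag in the rule vocabulary (missing columns = absent).
    ruleset
        Active rule table.
    admissions
        Admission records; defines which (patient, care-day) pairs exist.
    missing_day_policy
        ``"default_sc"`` (classify missing days as SC with a warning) or
        ``"error"``.

    Returns
    -------
    (acuity, report)
        ``acuity`` has one row per admitted care-day with columns
        patient_id, care_day, category, matched_rule_id; ``report`` counts
        care-days, missing days and the rule-file hash.
    """
    if missing_day_policy not in ("default_sc", "error"):
        raise ValueError(f"unknown missing_day_policy {missing_day_policy!r}")

    days = admitted_care_days(admissions)
    flag_cols = [c for c in interventions.columns if c in set(ruleset.vocabulary)]
    unknown_cols = [
        c
        for c in interventions.columns
        if c not in ("patient_id", "care_day") and c not in set(ruleset.vocabulary)
    ]
    if unknown_cols:
        raise RuleConfigError(f"unknown intervention flags: {sorted(unknown_cols)}")

    iv = interventions.copy()
    iv["care_day"] = pd.to_datetime(iv["care_day"]).dt.normalize()
    if iv.duplicated(["patient_id", "care_day"]).any():
        dups = iv[iv.duplicated(["patient_id", "care_day"], keep=False)]
        raise ValueError(
            "duplicate intervention records for: "
            f"{dups[['patient_id', 'care_day']].head(10).to_dict('records')}"
        )

    admitted = set(zip(days.patient_id, days.care_day))
    stray = [
        (p, d.date().isoformat())
        for p, d in zip(iv.patient_id, iv.care_day)
        if (p, d) not in admitted
    ]
    if stray:
        raise ValueError(
            f"{len(stray)} intervention record(s) outside any admission interval, "
            f"e.g. {stray[:10]}"
        )

    flag_lookup: dict[tuple, frozenset[str]] = {}
    for row in iv.itertuples(index=False):
        d = row._asdict()
        flag_lookup[(d["patient_id"], d["care_day"])] = frozenset(
            c for c in flag_cols if d[c]
        )

    records, missing = [], []
    for row in days.itertuples(index=False):
        key = (row.patient_id, row.care_day)
        if key in flag_lookup:
            category, rule_id = classify_day(flag_lookup[key], ruleset)
        else:
            if missing_day_policy == "error":
                raise ValueError(
                    f"no intervention record for patient {row.patient_id} on "
                    f"{row.care_day.date().isoformat()}"
                )
            missing.append(key)
            category, rule_id = ruleset.default_category, "missing_day_default"
        records.append((row.patient_id, row.care_day, category, rule_id))

    if missing:
        logger.warning(
            "%d admitted care-day(s) had no intervention record; classified as %s",
            len(missing),
            ruleset.default_category,
        )

    acuity = pd.DataFrame(
        records, columns=["patient_id", "care_day", "category", "matched_rule_id"]
    )
    report = {
        "care_days": len(acuity),
        "missing_intervention_days": len(missing),
        "rule_source_hash": ruleset.source_hash,
        "adapted": ruleset.adapted,
    }
    return acuity, report
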