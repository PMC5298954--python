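"""Criterion-variable coding and subject-exclusion rules.

Raw questionnaire answers are transformed into analysis-ready dependent
variables, each with a declared family (continuous, binary, ordinal), using a
declarative list of :class:`CodingRule` objects.  Out-of-domain raw values
(negative counts, percentages outside [0, 100], implausible height/weight)
are flagged as nonsense answers; rows are retained until the exclusion stage,
which applies the attention-based rules (catch-trial and matching-error
counts, minimum session duration for the retest sample).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "CodingRule",
    "CodedTable",
    "ExclusionReport",
    "STUDY1_RULES",
    "STUDY2_RULES",
    "apply_coding",
    "apply_study1_exclusions",
    "compute_bmi",
    "flag_nonsense",
]


# --------------------------------------------------------------------------
# coding rules
# --------------------------------------------------------------------------

_TRANSFORMS = {"log1p", "clipped_logit", "dichotomize", "ordinal",
               "log_positive_only", "sqrt", "identity", "bmi_dichotomize",
               "yes_no"}


@dataclass(frozen=True)
class CodingRule:
    """One criterion-variable transform.

    ``transform`` is one of: log1p, clipped_logit(lo, hi), dichotomize
    (threshold, direction), ordinal(edges), log_positive_only, sqrt,
    identity, bmi_dichotomize(threshold), yes_no.  ``condition_field`` (if
    set) restricts the rule to rows where that raw field equals
    ``condition_value`` (e.g. credit-card items apply to card users only);
    other rows are set to missing.
    """

    name: str
    source: str | tuple[str, ...]
    transform: str
    dv_family: str  # continuous | binary | ordinal
    params: dict = field(default_factory=dict)
    condition_field: str | None = None
    condition_value: object = None

    def __post_init__(self):
        if self.transform not in _TRANSFORMS:
            raise ConfigurationError(f"unknown transform {self.transform!r}")
        if self.dv_family not in {"continuous", "binary", "ordinal"}:
            raise ConfigurationError(f"unknown dv_family {self.dv_family!r}")
        if self.transform == "clipped_logit":
            lo = self.params.get("lo", 0.005)
            hi = self.params.get("hi", 0.995)
            if not (0.0 < lo < hi < 1.0):
                raise ConfigurationError(
                    f"clipped_logit bounds need 0 < lo < hi < 1, "
                    f"got ({lo}, {hi})")

    @classmethod
    def from_dict(cls, d: dict) -> "CodingRule":
        d = dict(d)
        if isinstance(d.get("source"), list):
            d["source"] = tuple(d["source"])
        return cls(**d)


def load_rules(path) -> list[CodingRule]:
    """Read a declarative rule list from a JSON or YAML file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return [CodingRule.from_dict(d) for d in data]


def compute_bmi(weight_kg, height_m):
    """Body mass index: weight in kilograms over squared height in meters."""
    return np.asarray(weight_kg, dtype=float) / np.asarray(height_m,
                                                           dtype=float) ** 2


def _apply_transform(rule: CodingRule, raw: pd.DataFrame) -> pd.Series:
    p = rule.params
    if rule.transform == "bmi_dichotomize":
        bmi = compute_bmi(raw[rule.source[1]], raw[rule.source[0]])
        out = (bmi >= p.get("threshold", 25.0)).astype(float)
        return pd.Series(out, index=raw.index)
    x = pd.to_numeric(raw[rule.source], errors="coerce")
    if rule.transform == "identity":
        return x.astype(float)
    if rule.transform == "log1p":
        return np.log1p(x)
    if rule.transform == "sqrt":
        return np.sqrt(x)
    if rule.transform == "log_positive_only":
        return pd.Series(np.where(x > 0, np.log(x.where(x > 0)), np.nan),
                         index=raw.index)
    if rule.transform == "clipped_logit":
        lo, hi = p.get("lo", 0.005), p.get("hi", 0.995)
        frac = (x / p.get("scale", 100.0)).clip(lo, hi)
        return np.log(frac / (1.0 - frac))
    if rule.transform == "dichotomize":
        thr = p.get("threshold", 0.0)
        if p.get("direction", "greater") == "greater":
            out = x > thr
        else:
            out = x >= thr
        return out.astype(float).where(x.notna())
    if rule.transform == "ordinal":
        edges = p["edges"]  # category j iff edges[j-1] <= x < edges[j]
        cat = np.digitize(x, edges).astype(float)
        return pd.Series(cat, index=raw.index).where(x.notna())
    if rule.transform == "yes_no":
        s = raw[rule.source].astype(str).str.strip().str.lower()
        out = s.map({"yes": 1.0, "no": 0.0})
        return out
    raise ConfigurationError(rule.transform)


# Default Study-1 codings: how each questionnaire item becomes a dependent
# variable.  Flossing uses three ordered categories (0 / 1-6 / 7+ per week);
# percentages are clipped to [0.005, 0.995] and logit-transformed; BMI is
# dichotomized at 25 ("overweight"); count items are dichotomized at > 0.
STUDY1_RULES = [
    CodingRule("exercise", "exercise_hours", "log1p", "continuous"),
    CodingRule("healthy_meals", "healthy_meals_pct", "clipped_logit",
               "continuous", {"lo": 0.005, "hi": 0.995, "scale": 100.0}),
    CodingRule("savings", "savings_pct", "clipped_logit", "continuous",
               {"lo": 0.005, "hi": 0.995, "scale": 100.0}),
    CodingRule("overweight", ("height_m", "weight_kg"), "bmi_dichotomize",
               "binary", {"threshold": 25.0}),
    CodingRule("tobacco", "tobacco", "yes_no", "binary"),
    CodingRule("gambling", "gambling_days", "dichotomize", "binary",
               {"threshold": 0.0, "direction": "greater"}),
    CodingRule("flossing", "floss_per_week", "ordinal", "ordinal",
               {"edges": [1, 7]}),
    CodingRule("cc_late_fees", "cc_late_fees", "dichotomize", "binary",
               {"threshold": 0.0, "direction": "greater"},
               condition_field="credit_card", condition_value="Yes"),
    CodingRule("cc_subpayment", "cc_subpayment_pct", "dichotomize", "binary",
               {"threshold": 0.0, "direction": "greater"},
               condition_field="credit_card", condition_value="Yes"),
    CodingRule("cigarettes", "packs_per_week", "log_positive_only",
               "continuous", condition_field="tobacco",
               condition_value="Yes"),
]


def _study2_rules() -> list[CodingRule]:
    # Declarative reproduction of the Study-2 scale column: binary items pass
    # through, heavy-tailed positive quantities are logged on their nonzero
    # subset, income is square-rooted, sleep and age-of-debut stay raw.
    from .synthetic_data import STUDY2_BINARY_SPECS, STUDY2_CONTINUOUS_SPECS
    rules = [CodingRule(name, name, "identity", "binary")
             for name, _, _ in STUDY2_BINARY_SPECS]
    scale_map = {
        "exercise_light_min_y": "log_positive_only",
        "exercise_vigorous_min_y": "log_positive_only",
        "sleep_min_weekday": "identity",
        "sleep_min_weekend": "identity",
        "drinks_last_month": "log_positive_only",
        "sexual_debut": "identity",
        "net_family_income": "sqrt",
        "cc_debt_dollars": "log_positive_only",
    }
    for name, *_ in STUDY2_CONTINUOUS_SPECS:
        rules.append(CodingRule(name, name, scale_map[name], "continuous"))
    return rules


STUDY2_RULES = _study2_rules()


@dataclass
class CodedTable:
    """Coded criterion variables with declared DV families."""

    frame: pd.DataFrame
    dv_family: dict[str, str]
    nonsense: pd.Series  # per-row flag: any out-of-domain raw answer

    def schema(self) -> dict:
        return {"columns": self.dv_family}

    def to_csv(self, path, schema_path=None):
        self.frame.to_csv(path, index=False)
        if schema_path is not None:
            Path(schema_path).write_text(json.dumps(self.schema(), indent=2))


# Configurable physiologic bounds for the nonsense-answer screen.
DEFAULT_DOMAIN_BOUNDS = {
    "height_m": (1.0, 2.5),
    "weight_kg": (25.0, 350.0),
    "age": (18, 110),
    "percent": (0.0, 100.0),
    "count_max": 10000,
}

_PERCENT_FIELDS = ("healthy_meals_pct", "cc_subpayment_pct", "savings_pct")
_COUNT_FIELDS = ("exercise_hours", "floss_per_week", "cc_late_fees",
                 "gambling_days", "packs_per_week")


def flag_nonsense(raw: pd.DataFrame, bounds: dict | None = None) -> pd.Series:
    """Flag rows with out-of-domain raw answers (the nonsense-answer rule).

    Negative counts, percentages outside [0, 100], and height/weight/age
    outside configurable physiologic bounds all trigger the flag.  Missing
    values never do.
    """
    b = dict(DEFAULT_DOMAIN_BOUNDS)
    if bounds:
        b.update(bounds)
    bad = pd.Series(False, index=raw.index)
    for col in _PERCENT_FIELDS:
        if col in raw:
            x = pd.to_numeric(raw[col], errors="coerce")
            lo, hi = b["percent"]
            bad |= ((x < lo) | (x > hi)).fillna(False)
    for col in _COUNT_FIELDS:
        if col in raw:
            x = pd.to_numeric(raw[col], errors="coerce")
            bad |= ((x < 0) | (x > b["count_max"])).fillna(False)
    for col in ("height_m", "weight_kg", "age"):
        if col in raw:
            x = pd.to_numeric(raw[col], errors="coerce")
            lo, hi = b[col]
            bad |= ((x < lo) | (x > hi)).fillna(False)
    return bad


def apply_coding(raw: pd.DataFrame, rules: list[CodingRule] | None = None,
                 bounds: dict | None = None) -> CodedTable:
    """Apply coding rules to a raw questionnaire table.

    Produces one output column per rule with its DV family recorded, plus the
    per-row nonsense flag.  Conditional rules (credit-card items, smoker-only
    items) yield missing values outside their subpopulation.
    """
    if rules is None:
        rules = STUDY1_RULES
    missing = [r.name for r in rules
               for src in ([r.source] if isinstance(r.source, str)
                           else list(r.source))
               if src not in raw.columns]
    if missing:
        raise InputError(f"missing source fields for rules: {missing}")
    out = {}
    families = {}
    for rule in rules:
        coded = _apply_transform(rule, raw)
        if rule.condition_field is not None:
            mask = raw[rule.condition_field] == rule.condition_value
            coded = coded.where(mask)
        out[rule.name] = coded
        families[rule.name] = rule.dv_family
    frame = pd.DataFrame(out, index=raw.index)
    if "subject_id" in raw.columns:
        frame.insert(0, "subject_id", raw["subject_id"])
    return CodedTable(frame, families, flag_nonsense(raw, bounds))


# --------------------------------------------------------------------------
# exclusions
# --------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    """Per-subject exclusion flags and the deduplicated accounting."""

    flags: pd.DataFrame  # subject_id, nonsense_answer, catch_failures,
    #                      matching_errors, session2_minutes, excluded,
    #                      excluded_retest, reasons
    counts: dict[str, int]

    @property
    def n_excluded(self) -> int:
        return int(self.flags["excluded"].sum())

    def main_sample(self) -> pd.Index:
        keep = ~self.flags["excluded"]
        return pd.Index(self.flags.loc[keep, "subject_id"])

    def retest_sample(self) -> pd.Index:
        keep = ~self.flags["excluded"] & ~self.flags["excluded_retest"]
        if "in_session2" in self.flags:
            keep &= self.flags["in_session2"]
        return pd.Index(self.flags.loc[keep, "subject_id"])


def apply_study1_exclusions(raw: pd.DataFrame, trial_log: pd.DataFrame,
                            session2_minutes: pd.Series | None = None,
                            catch_threshold: int = 3,
                            matching_threshold: int = 3,
                            min_session2_minutes: float = 3.0,
                            nonsense: pd.Series | None = None,
                            expected_catch: int = 8,
                            expected_matching: int = 40) -> ExclusionReport:
    """Apply the Study-1 subject-exclusion rules.

    A subject is excluded from the main sample if they gave a nonsense
    questionnaire answer, took the designated wrong option in >= 3 of the 8
    session-1 catch trials, or gave LL < SS in >= 3 of the 40 session-1
    matching trials.  The retest sample additionally drops subjects who
    completed session 2 in under 3 minutes.  ``trial_log`` must be the tidy
    session-1 trial frame (as built by ``trials_to_frame``), covering the
    catch and matching trials for every subject.
    """
    if "subject_id" not in trial_log.columns:
        raise InputError("trial_log must carry a subject_id column")
    ids = raw["subject_id"]

    catch = trial_log[trial_log["is_catch"] &
                      (trial_log["family"] == "bisection")]
    n_catch = catch.groupby("subject_id").size()
    if not (n_catch.reindex(ids).fillna(0) == expected_catch).all():
        raise InputError(
            f"trial_log must cover {expected_catch} catch trials per subject")
    # catch failure: wrong option given the dominated direction
    ratio = catch["ss_amount"] / catch["ll_amount"]
    wrong = np.where(ratio < 1.0, "SS", "LL")
    failures = (catch["response"].to_numpy() == wrong)
    catch_failures = (pd.Series(failures, index=catch["subject_id"])
                      .groupby(level=0).sum().reindex(ids).fillna(0)
                      .astype(int))

    matching = trial_log[trial_log["family"] == "matching"]
    n_match = matching.groupby("subject_id").size()
    if not (n_match.reindex(ids).fillna(0) == expected_matching).all():
        raise InputError(
            f"trial_log must cover {expected_matching} matching trials "
            f"per subject")
    matching_errors = (matching.groupby("subject_id")["is_error"].sum()
                       .reindex(ids).fillna(0).astype(int))

    if nonsense is None:
        nonsense = flag_nonsense(raw)
    nonsense = nonsense.set_axis(ids).astype(bool)

    flags = pd.DataFrame({
        "subject_id": ids.to_numpy(),
        "nonsense_answer": nonsense.to_numpy(),
        "catch_failures": catch_failures.to_numpy(),
        "matching_errors": matching_errors.to_numpy(),
    })
    flags["excluded"] = (flags["nonsense_answer"]
                         | (flags["catch_failures"] >= catch_threshold)
                         | (flags["matching_errors"] >= matching_threshold))
    if session2_minutes is not None:
        s2 = session2_minutes.reindex(ids.to_numpy())
        flags["in_session2"] = s2.notna().to_numpy()
        flags["session2_minutes"] = s2.to_numpy()
        flags["excluded_retest"] = (s2 < min_session2_minutes).fillna(
            False).to_numpy()
    else:
        flags["excluded_retest"] = False

    def _reasons(row):
        r = []
        if row["nonsense_answer"]:
            r.append("nonsense_answer")
        if row["catch_failures"] >= catch_threshold:
            r.append("catch_failures")
        if row["matching_errors"] >= matching_threshold:
            r.append("matching_errors")
        return r

    flags["reasons"] = flags.apply(_reasons, axis=1)
    counts = {
        "nonsense_answer": int(flags["nonsense_answer"].sum()),
        "catch_failures": int((flags["catch_failures"]
                               >= catch_threshold).sum()),
        "matching_errors": int((flags["matching_errors"]
                                >= matching_threshold).sum()),
        "excluded_total": int(flags["excluded"].sum()),
        "excluded_retest_only": int((~flags["excluded"]
                                     & flags["excluded_retest"]).sum()),
    }
    return ExclusionReport(flags, counts)
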