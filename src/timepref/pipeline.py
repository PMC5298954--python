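"""End-to-end orchestration: simulate -> administer -> code -> evaluate.

``run_study1_pipeline`` simulates a cohort, administers the six preference
tests (three families x near/far) over three rounds with per-subject random
test order, applies the criterion codings and exclusion rules, and emits the
descriptive, association-versus-prediction, reliability, nonstationarity and
cross-prediction tables.  ``run_study2_pipeline`` generates patience pairs
plus the 40-column criterion block, runs the nonparametric association tests
with Holm correction, and assesses the log and nominal models.

A single global seed is fanned out to per-stage, per-subject, per-round
generators via ``np.random.default_rng([seed, stage, ...])`` so every stage
is independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cv_coding import (CodedTable, STUDY1_RULES, STUDY2_RULES, apply_coding,
                        apply_study1_exclusions)
from .errors import DegenerateOutcomeError, FittingError, InputError
from .evaluation import (ModelSpec, assess_prediction, describe_scores,
                         design_matrix_study1, nonstationarity_counts,
                         reliability_report)
from .preference_tests import (FixedItemBank, run_bisection_test,
                               run_fixed_test, run_matching_test,
                               trials_to_frame)
from .study2_models import holm_bonferroni, rank_tests, study2_assess
from .synthetic_data import (SimulationConfig, generate_cohort,
                             generate_study1_criteria,
                             generate_study2_responses,
                             simulate_binary_choice,
                             simulate_matching_response)

__all__ = [
    "RunManifest",
    "ReportBundle",
    "make_choice_callback",
    "make_matching_callback",
    "administer_round",
    "study1_association_prediction",
    "run_study1_pipeline",
    "run_study2_pipeline",
    "rerun_from_manifest",
]

logger = logging.getLogger(__name__)

FAMILIES = ("fixed", "bisection", "matching")
VARIANTS = ("near", "far")

# stage ids for seed fan-out
_STAGE_ADMIN = 1
_STAGE_CRITERIA = 2
_STAGE_SESSION2 = 3
_STAGE_EVAL = 4
_STAGE_STUDY2 = 5


@dataclass
class RunManifest:
    """Traceability record for one pipeline run."""

    config: dict
    seed: int
    version: str
    stage_rows: dict = field(default_factory=dict)
    output_paths: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        d = json.loads(text)
        return cls(config=d["config"], seed=d["seed"], version=d["version"],
                   stage_rows=d.get("stage_rows", {}),
                   output_paths=d.get("output_paths", {}))


def rerun_from_manifest(manifest: RunManifest, study: str = "study1",
                        **kwargs) -> "ReportBundle":
    """Reproduce a bundle bit-for-bit from its manifest's config snapshot."""
    config = SimulationConfig.from_dict(manifest.config)
    if study == "study1":
        return run_study1_pipeline(config, **kwargs)
    if study == "study2":
        return run_study2_pipeline(config, **kwargs)
    raise ValueError(f"unknown study {study!r}")


@dataclass
class ReportBundle:
    """Named tables plus the manifest that produced them."""

    tables: dict
    manifest: RunManifest

    def write(self, out_dir):
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            path = out / f"{name}.csv"
            if isinstance(table, pd.DataFrame):
                table.to_csv(path, index=False)
            else:
                path = out / f"{name}.json"
                path.write_text(json.dumps(table, indent=2, default=str))
            self.manifest.output_paths[name] = str(path)
        (out / "manifest.json").write_text(self.manifest.to_json())


# --------------------------------------------------------------------------
# respondent callbacks
# --------------------------------------------------------------------------

def make_choice_callback(profile, horizon: str, rng: np.random.Generator):
    """Forced-choice callback for the fixed and bisection tests.

    Regular items go through the consistency-based choice model; dominated
    catch items are answered correctly except for rare attention lapses
    (``catch_error_rate``).
    """
    def respond(item):
        if item.is_catch:
            ratio = item.ss_amount / item.ll_amount
            correct = "LL" if ratio < 1.0 else "SS"
            if rng.random() < profile.catch_error_rate:
                return "SS" if correct == "LL" else "LL"
            return correct
        return simulate_binary_choice(profile, item.ss_amount,
                                      item.ll_amount, horizon, rng)
    return respond


def make_matching_callback(profile, horizon: str, rng: np.random.Generator):
    def respond(prompt):
        return simulate_matching_response(profile, prompt.ss_amount, horizon,
                                          rng)
    return respond


# --------------------------------------------------------------------------
# administration
# --------------------------------------------------------------------------

def _administer_one(profile, family, variant, bank, rng):
    if family == "fixed":
        return run_fixed_test(make_choice_callback(profile, variant, rng),
                              variant, bank=bank)
    if family == "bisection":
        return run_bisection_test(make_choice_callback(profile, variant, rng),
                                  variant, rng=rng)
    return run_matching_test(make_matching_callback(profile, variant, rng),
                             variant, rng=rng)


def administer_round(cohort, seed: int, round_index: int,
                     bank: FixedItemBank | None = None):
    """Administer all six tests to every subject in randomized order.

    Returns (scores, trial_log): one score row per subject x family x
    variant, and the tidy concatenated trial log.
    """
    if bank is None:
        bank = FixedItemBank.default()
    score_rows, log_frames = [], []
    tests = [(f, v) for f in FAMILIES for v in VARIANTS]
    for i, profile in enumerate(cohort):
        rng = np.random.default_rng([seed, _STAGE_ADMIN, round_index, i])
        order = rng.permutation(len(tests))
        results = []
        for j in order:
            family, variant = tests[j]
            res = _administer_one(profile, family, variant, bank, rng)
            results.append(res)
            score_rows.append({
                "subject_id": profile.subject_id, "round": round_index,
                "family": family, "variant": variant, "score": res.score,
                "catch_failures": res.catch_failures,
                "error_trials": res.error_trials,
            })
        log_frames.append(trials_to_frame(results,
                                          subject_id=profile.subject_id,
                                          round=round_index))
    return pd.DataFrame(score_rows), pd.concat(log_frames, ignore_index=True)


def _scores_wide(scores: pd.DataFrame, round_index: int) -> pd.DataFrame:
    sub = scores[scores["round"] == round_index]
    return sub.pivot_table(index="subject_id", columns=["family", "variant"],
                           values="score", sort=False)


# --------------------------------------------------------------------------
# Study-1 evaluation tables
# --------------------------------------------------------------------------

_FAMILY_TO_SPEC = {"continuous": "continuous", "binary": "binary",
                   "ordinal": "ordinal"}


def study1_association_prediction(scores_wide: pd.DataFrame,
                                  coded: CodedTable, k: int = 10,
                                  seed: int = 0) -> pd.DataFrame:
    """Association and tenfold predictive accuracy per test family x CV.

    For each criterion, the four-term model (intercept, near, far,
    interaction) of each family's round-1 scores is fit in-sample and
    cross-validated; rows missing on the CV (non-cardholders for the credit
    items, nonsmokers for cigarettes) are dropped per criterion.
    """
    frame = coded.frame.set_index("subject_id") \
        if "subject_id" in coded.frame else coded.frame
    frame = frame.loc[scores_wide.index]
    rows = []
    for test_family in FAMILIES:
        near = scores_wide[(test_family, "near")].to_numpy(float)
        far = scores_wide[(test_family, "far")].to_numpy(float)
        for cv, dv_family in coded.dv_family.items():
            y = pd.to_numeric(frame[cv], errors="coerce").to_numpy(float)
            mask = np.isfinite(y) & np.isfinite(near) & np.isfinite(far)
            n = int(mask.sum())
            k_eff = min(k, n)
            if k_eff < k:
                logger.warning("reducing folds to %d for CV %s (n=%d)",
                               k_eff, cv, n)
            X = design_matrix_study1(near[mask], far[mask])
            try:
                a = assess_prediction(ModelSpec(_FAMILY_TO_SPEC[dv_family]),
                                      X, y[mask], k=k_eff, seed=seed)
            except (FittingError, DegenerateOutcomeError, InputError) as exc:
                logger.warning("skipping %s x %s: %s", test_family, cv, exc)
                rows.append({"test_family": test_family, "cv": cv,
                             "dv_family": dv_family, "n": n,
                             "association": np.nan, "predictive": np.nan,
                             "baseline": np.nan, "note": str(exc)})
                continue
            rows.append({"test_family": test_family, "cv": cv,
                         "dv_family": dv_family, "n": a.n,
                         "association": a.association,
                         "association_metric": a.association_metric,
                         "predictive": a.predictive,
                         "predictive_metric": a.predictive_metric,
                         "baseline": a.baseline,
                         "baseline_metric": a.baseline_metric,
                         "beats_baseline": a.beats_baseline(), "note": ""})
    return pd.DataFrame(rows)


def _reliability_table(wide_pred: pd.DataFrame, wide_targ: pd.DataFrame,
                       ids: pd.Index, label: str) -> pd.DataFrame:
    rows = []
    common = ids.intersection(wide_pred.index).intersection(wide_targ.index)
    for family in FAMILIES:
        for variant in VARIANTS:
            rep = reliability_report(
                wide_pred.loc[common, (family, variant)],
                wide_targ.loc[common, (family, variant)])
            rows.append({"interval": label, "family": family,
                         "variant": variant, **rep.__dict__})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# pipelines
# --------------------------------------------------------------------------

def run_study1_pipeline(config: SimulationConfig, k_folds: int = 10,
                        rounds: int = 3) -> ReportBundle:
    """The full simulated study: cohort, 6 tests x 3 rounds, coding,
    exclusions, and the five evaluation tables."""
    manifest = RunManifest(config.to_dict(), config.seed, __version__)
    cohort = generate_cohort(config)
    manifest.stage_rows["cohort"] = len(cohort)

    all_scores, logs = [], []
    for r in range(1, rounds + 1):
        scores_r, log_r = administer_round(cohort, config.seed, r)
        all_scores.append(scores_r)
        logs.append(log_r)
    scores = pd.concat(all_scores, ignore_index=True)
    trial_log = pd.concat(logs, ignore_index=True)
    manifest.stage_rows["score_rows"] = len(scores)
    manifest.stage_rows["trial_rows"] = len(trial_log)

    rng_crit = np.random.default_rng([config.seed, _STAGE_CRITERIA])
    raw = generate_study1_criteria(cohort, config, rng_crit)
    coded = apply_coding(raw, STUDY1_RULES)

    # session 1 comprises rounds 1 and 2; session 2 is round 3
    rng_s2 = np.random.default_rng([config.seed, _STAGE_SESSION2])
    session2_minutes = pd.Series(
        np.exp(rng_s2.normal(np.log(6.0), 0.45, len(cohort))),
        index=[p.subject_id for p in cohort])
    session1_log = trial_log[trial_log["round"].isin([1, 2])]
    exclusions = apply_study1_exclusions(raw, session1_log, session2_minutes)
    main_ids = exclusions.main_sample()
    retest_ids = exclusions.retest_sample()
    manifest.stage_rows["main_sample"] = len(main_ids)
    manifest.stage_rows["retest_sample"] = len(retest_ids)

    wide = {r: _scores_wide(scores, r) for r in range(1, rounds + 1)}
    w1 = wide[1].loc[wide[1].index.intersection(main_ids)]

    table1 = pd.DataFrame([
        {"family": f, "variant": v, **describe_scores(w1[(f, v)])}
        for f in FAMILIES for v in VARIANTS])

    eval_seed = int(np.random.default_rng(
        [config.seed, _STAGE_EVAL]).integers(2 ** 31))
    k_eff = min(k_folds, len(w1))
    if k_eff < k_folds:
        logger.warning("small sample: reducing k_folds to %d", k_eff)
    table2 = study1_association_prediction(w1, coded, k=k_eff,
                                           seed=eval_seed)

    tables3 = [_reliability_table(wide[1], wide[2], main_ids, "round2")]
    if rounds >= 3:
        tables3.append(_reliability_table(wide[1], wide[3], retest_ids,
                                          "round3"))
    table3 = pd.concat(tables3, ignore_index=True)

    table4 = pd.DataFrame([
        {"family": f, **nonstationarity_counts(w1[(f, "near")],
                                               w1[(f, "far")])}
        for f in FAMILIES])

    # round-1 near scores predicting round-2 far scores
    rows5 = []
    common = main_ids.intersection(wide[1].index).intersection(wide[2].index)
    for f in FAMILIES:
        rep = reliability_report(wide[1].loc[common, (f, "near")],
                                 wide[2].loc[common, (f, "far")])
        rows5.append({"family": f, **rep.__dict__})
    table5 = pd.DataFrame(rows5)

    tables = {
        "table1_descriptives": table1,
        "table2_association_prediction": table2,
        "table3_reliability": table3,
        "table4_nonstationarity": table4,
        "table5_near_predicts_far": table5,
        "exclusions": exclusions.flags.drop(columns=["reasons"]),
        "exclusion_counts": exclusions.counts,
    }
    return ReportBundle(tables, manifest)


def run_study2_pipeline(config: SimulationConfig, k_folds: int = 10,
                        cv_names: list[str] | None = None) -> ReportBundle:
    """Patience pairs + 40 criteria: rank tests with Holm correction and the
    log-versus-nominal association/prediction comparison.

    ``cv_names`` restricts the analysis to a subset of criterion variables;
    an empty list yields an empty (but well-formed) report.
    """
    manifest = RunManifest(config.to_dict(), config.seed, __version__)
    cohort = generate_cohort(config)
    rng = np.random.default_rng([config.seed, _STAGE_STUDY2])
    responses = generate_study2_responses(cohort, config, rng)
    manifest.stage_rows["subjects"] = len(responses)

    rules = STUDY2_RULES if cv_names is None else \
        [r for r in STUDY2_RULES if r.name in set(cv_names)]
    coded = apply_coding(responses, rules)
    families = coded.dv_family
    frame = coded.frame

    # nonparametric association tests: one per CV per patience item
    test_rows = []
    for name, fam in families.items():
        for item in ("month_amount", "year_amount"):
            try:
                p = rank_tests(responses[item], frame[name], fam)
            except DegenerateOutcomeError as exc:
                logger.warning("rank test skipped for %s x %s: %s",
                               name, item, exc)
                continue
            test_rows.append({"cv": name, "dv_family": fam,
                              "patience_item": item, "p_value": p})
    test_table = pd.DataFrame(test_rows)
    summary = {"families": {}}
    if len(test_table):
        for fam in ("binary", "continuous"):
            sub = test_table[test_table["dv_family"] == fam]
            if not len(sub):
                continue
            reject = holm_bonferroni(sub["p_value"].to_numpy())
            test_table.loc[sub.index, "holm_reject"] = reject
            summary["families"][fam] = {
                "family_size": int(len(sub)),
                "n_significant_unadjusted":
                    int((sub["p_value"] < 0.05).sum()),
                "n_significant_holm": int(reject.sum()),
            }

    eval_seed = int(np.random.default_rng(
        [config.seed, _STAGE_EVAL]).integers(2 ** 31))
    pairs = responses[["month_amount", "year_amount"]]
    assessment = study2_assess(pairs, frame, families, k=k_folds,
                               seed=eval_seed)

    tables = {
        "table7_8_models": assessment,
        "rank_tests": test_table,
        "test_summary": summary,
    }
    return ReportBundle(tables, manifest)
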