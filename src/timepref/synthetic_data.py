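"""Seeded synthetic respondents for exercising the time-preference pipeline.

Respondents carry latent monthly discount factors ``d_near`` (no front-end
delay) and ``d_far`` (1-month front-end delay), a choice-consistency
probability, and a standardized latent trait ``latent_z`` that drives every
criterion variable.  ``latent_z`` is the Gauss-transformed rank of ``d_near``,
so it is exactly standard normal and perfectly rank-correlated with patience;
criterion variables load on it with a coefficient calibrated so that the
in-sample Efron's R-squared of the corresponding probit regression equals the
configured ``effect_size`` in population.

Two questionnaire blocks are generated:

* a Study-1-style block (tobacco, exercise, flossing, credit items, height and
  weight, ...) in the raw response formats that the coding stage expects, and
* a Study-2-style block: paired nonnegative-integer "smallest extra amount to
  wait" responses for a $1000 prize at 1 month and 1 year (zero-inflated
  lognormal) plus 40 binary/continuous criterion columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, InputError

__all__ = [
    "RespondentProfile",
    "SimulationConfig",
    "generate_cohort",
    "simulate_binary_choice",
    "simulate_matching_response",
    "generate_study1_criteria",
    "generate_study2_responses",
    "binary_loading",
    "cohort_to_frame",
    "STUDY2_BINARY_SPECS",
    "STUDY2_CONTINUOUS_SPECS",
]


# --------------------------------------------------------------------------
# profiles and configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RespondentProfile:
    """Latent parameters of one simulated respondent.

    ``d_near`` and ``d_far`` are monthly discount factors in (0, 1]: the
    present value of $1 delivered one month later, without and with a 1-month
    front-end delay.  ``choice_consistency`` is the probability of choosing
    the truly preferred option in a forced choice; ``catch_error_rate`` is the
    (much smaller) probability of taking the designated wrong option on a
    dominated catch trial, modelling the fact that attention lapses on
    obvious items are rarer than inconsistency near indifference.
    """

    subject_id: str
    d_near: float
    d_far: float
    choice_consistency: float = 0.75
    matching_jitter_sd: float = 0.05
    catch_error_rate: float = 0.05
    latent_z: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.d_near <= 1.0 and 0.0 < self.d_far <= 1.0):
            raise ConfigurationError(
                f"discount factors must lie in (0, 1]: "
                f"d_near={self.d_near}, d_far={self.d_far}")
        if not (0.5 < self.choice_consistency <= 1.0):
            raise ConfigurationError(
                f"choice_consistency must lie in (0.5, 1]: "
                f"{self.choice_consistency}")
        if self.matching_jitter_sd < 0:
            raise ConfigurationError("matching_jitter_sd must be >= 0")

    def discount_factor(self, horizon: str) -> float:
        if horizon == "near":
            return self.d_near
        if horizon == "far":
            return self.d_far
        raise InputError(f"horizon must be 'near' or 'far', got {horizon!r}")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the observed study structure: 181 analyzable respondents,
    choice consistency 3/4 (matching the bisection test's assumed response
    reliability), discount factors Beta-distributed with median near 0.7, and
    weak criterion coupling on the Efron's-R-squared ~ 0.03 scale.
    """

    n_subjects: int = 181
    effect_size: float = 0.03
    choice_consistency: float = 0.75
    matching_jitter_sd: float = 0.05
    catch_error_rate: float = 0.05
    # d_near ~ Beta(beta_a, beta_b): mean 0.7, median ~0.72
    beta_a: float = 3.5
    beta_b: float = 1.5
    # fraction of subjects whose far discount factor differs from the near one
    nonstationary_fraction: float = 0.8
    nonstationarity_sd: float = 0.15
    nonstationarity_shift: float = -0.02
    # Study-2 patience-pair response model
    zero_inflation: float = 0.1
    lognormal_mu: float = 5.0
    lognormal_sigma: float = 1.5
    patience_loading: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not (0.0 <= self.effect_size < 1.0):
            raise ConfigurationError("effect_size must lie in [0, 1)")
        if not (0.0 <= self.zero_inflation < 1.0):
            raise ConfigurationError("zero_inflation must lie in [0, 1)")
        if not (0.5 < self.choice_consistency <= 1.0):
            raise ConfigurationError("choice_consistency must lie in (0.5, 1]")
        if not (0.0 <= self.nonstationary_fraction <= 1.0):
            raise ConfigurationError("nonstationary_fraction must lie in [0, 1]")
        if min(self.beta_a, self.beta_b) <= 0:
            raise ConfigurationError("beta_a and beta_b must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Read a config from a JSON or YAML file."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig) -> list[RespondentProfile]:
    """Draw a seeded cohort of respondent profiles.

    ``d_near`` is Beta(beta_a, beta_b) truncated away from 0; ``latent_z`` is
    its Gaussian rank transform.  A configured fraction of subjects is
    nonstationary: their ``d_far`` is ``d_near`` plus Gaussian drift (with a
    small negative shift by default, matching the mild observed tendency to
    plan to be *less* patient later); the rest have ``d_far == d_near``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    d_near = rng.beta(config.beta_a, config.beta_b, size=n)
    d_near = np.clip(d_near, 1e-6, 1.0)
    latent_z = stats.norm.ppf(
        stats.beta.cdf(d_near, config.beta_a, config.beta_b))
    latent_z = np.clip(latent_z, -8.0, 8.0)

    nonstat = rng.random(n) < config.nonstationary_fraction
    drift = rng.normal(config.nonstationarity_shift,
                       config.nonstationarity_sd, size=n)
    d_far = np.where(nonstat, np.clip(d_near + drift, 1e-6, 1.0), d_near)

    return [
        RespondentProfile(
            subject_id=f"s{i:04d}",
            d_near=float(d_near[i]),
            d_far=float(d_far[i]),
            choice_consistency=config.choice_consistency,
            matching_jitter_sd=config.matching_jitter_sd,
            catch_error_rate=config.catch_error_rate,
            latent_z=float(latent_z[i]),
        )
        for i in range(n)
    ]


def cohort_to_frame(cohort: list[RespondentProfile]) -> pd.DataFrame:
    """Tabular view of a cohort (one row per subject), CSV-ready."""
    return pd.DataFrame([asdict(p) for p in cohort])


# --------------------------------------------------------------------------
# choice and matching behavior
# --------------------------------------------------------------------------

def simulate_binary_choice(profile: RespondentProfile, ss_amount: float,
                           ll_amount: float, horizon: str,
                           rng: np.random.Generator) -> str:
    """One forced choice between an SS and an LL reward.

    The respondent prefers LL iff ``d * ll_amount > ss_amount`` (with ``d``
    the horizon's discount factor), resolves exact indifference by a fair
    coin, and complies with the preference with probability
    ``choice_consistency``.
    """
    if ss_amount <= 0 or ll_amount <= 0:
        raise InputError("reward amounts must be positive")
    d = profile.discount_factor(horizon)
    discounted = d * ll_amount
    if discounted > ss_amount:
        preferred = "LL"
    elif discounted < ss_amount:
        preferred = "SS"
    else:
        preferred = "LL" if rng.random() < 0.5 else "SS"
    if rng.random() < profile.choice_consistency:
        return preferred
    return "SS" if preferred == "LL" else "LL"


def simulate_matching_response(profile: RespondentProfile, ss_amount: float,
                               horizon: str,
                               rng: np.random.Generator) -> float:
    """Fill-in-the-blank LL amount that the respondent reports as indifferent.

    The noiseless answer is ``ss / d``; multiplicative lognormal jitter with
    log-sd ``matching_jitter_sd`` (median 1) is applied and the result rounded
    to cents.  Always strictly positive.
    """
    if ss_amount <= 0:
        raise InputError("ss_amount must be positive")
    d = profile.discount_factor(horizon)
    noise = float(np.exp(rng.normal(0.0, profile.matching_jitter_sd))) \
        if profile.matching_jitter_sd > 0 else 1.0
    ll = round(ss_amount / d * noise, 2)
    return max(ll, 0.01)


# --------------------------------------------------------------------------
# criterion coupling calibration
# --------------------------------------------------------------------------

@lru_cache(maxsize=512)
def binary_loading(effect_size: float, p_positive: float) -> float:
    """Latent variance share lambda for a dichotomous criterion.

    The criterion is ``y = 1[sqrt(lam) * z + sqrt(1 - lam) * eps >= c]`` with
    ``c`` set by the positive rate.  The population Efron's R-squared of the
    probit of y on z is ``(Phi2(m, m; lam) - Phi(m)^2) / (Phi(m)(1 - Phi(m)))``
    with ``m = Phi^{-1}(p_positive)``; this solves for ``lam`` so that the
    statistic equals ``effect_size``.
    """
    if effect_size <= 0:
        return 0.0
    if not (0 < p_positive < 1):
        raise ConfigurationError("p_positive must lie in (0, 1)")
    m = stats.norm.ppf(p_positive)
    denom = p_positive * (1.0 - p_positive)

    def efron(lam):
        cov = [[1.0, lam], [lam, 1.0]]
        p2 = stats.multivariate_normal.cdf([m, m], mean=[0, 0], cov=cov)
        return (p2 - p_positive ** 2) / denom

    if efron(0.999999) < effect_size:
        raise ConfigurationError(
            f"effect_size {effect_size} unattainable at rate {p_positive}")
    return float(optimize.brentq(
        lambda lam: efron(lam) - effect_size, 1e-12, 0.999999, xtol=1e-10))


def _latent(z, lam, sign, rng):
    """sign * sqrt(lam) * z + sqrt(1 - lam) * independent noise."""
    eps = rng.standard_normal(len(z))
    return sign * np.sqrt(lam) * z + np.sqrt(1.0 - lam) * eps


def _count_from_latent(u, threshold, growth=1.0, scale=3.0):
    """Monotone map latent -> nonnegative integer count, zero below threshold."""
    pos = u >= threshold
    mag = 1 + np.round(np.expm1(growth * (u - threshold)) * scale)
    return np.where(pos, mag, 0.0).astype(int)


# --------------------------------------------------------------------------
# Study-1 criterion questionnaire
# --------------------------------------------------------------------------

def generate_study1_criteria(cohort: list[RespondentProfile],
                             config: SimulationConfig,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Raw questionnaire answers for a Study-1-style criterion block.

    One row per subject, in the response formats the questionnaire used
    (Yes/No strings, integers, percentages, metric height and weight).  Each
    health/financial item loads on ``latent_z`` with a sign that makes higher
    patience "healthier" and a loading calibrated to ``config.effect_size``;
    with ``effect_size == 0`` every item is independent of all latents.
    """
    if not cohort:
        raise InputError("cohort must be nonempty")
    es = config.effect_size
    z = np.array([p.latent_z for p in cohort])
    n = len(cohort)

    out = {"subject_id": [p.subject_id for p in cohort]}

    female = rng.random(n) < 0.37
    out["sex"] = np.where(female, "Female", "Male")
    out["age"] = np.clip(np.round(np.exp(rng.normal(np.log(31), 0.3, n))),
                         18, 75).astype(int)
    height = np.where(female, rng.normal(1.62, 0.06, n),
                      rng.normal(1.76, 0.07, n))
    out["height_m"] = np.round(np.clip(height, 1.4, 2.1), 2)

    # overweight latent: BMI 25.8 +/- 5, dichotomized downstream at 25
    lam = binary_loading(es, stats.norm.cdf((25.8 - 25.0) / 5.0))
    bmi = 25.8 + 5.0 * _latent(z, lam, -1, rng)
    out["weight_kg"] = np.round(np.clip(bmi, 14, 60) * height ** 2, 1)

    lam = binary_loading(es, 0.24)
    tobacco = _latent(z, lam, -1, rng) >= stats.norm.ppf(1 - 0.24)
    out["tobacco"] = np.where(tobacco, "Yes", "No")
    packs = np.round(np.expm1(1.8 + 0.6 * _latent(z, es, -1, rng)))
    out["packs_per_week"] = np.where(tobacco, np.clip(packs, 0, 70), 0).astype(int)

    hours = np.round(np.expm1(1.2 + 0.9 * _latent(z, es, +1, rng)))
    out["exercise_hours"] = np.clip(hours, 0, 80).astype(int)

    out["healthy_meals_pct"] = np.clip(
        np.round(100 * stats.norm.cdf(1.2 * _latent(z, es, +1, rng))),
        0, 100).astype(int)

    floss = _count_from_latent(_latent(z, es, +1, rng), -0.55, 0.9, 3.0)
    out["floss_per_week"] = np.clip(floss, 0, 28)

    cc_user = rng.random(n) < 0.8
    out["credit_card"] = np.where(cc_user, "Yes", "No")
    lam = binary_loading(es, 0.25)
    fees = _count_from_latent(_latent(z, lam, -1, rng),
                              stats.norm.ppf(0.75), 0.8, 2.0)
    out["cc_late_fees"] = np.where(cc_user, fees, np.nan)
    lam = binary_loading(es, 0.40)
    sub_latent = _latent(z, lam, -1, rng)
    sub_pos = sub_latent >= stats.norm.ppf(0.60)
    sub_pct = np.clip(np.round(100 * stats.norm.cdf(0.5 + sub_latent)), 1, 100)
    out["cc_subpayment_pct"] = np.where(cc_user,
                                        np.where(sub_pos, sub_pct, 0), np.nan)

    out["savings_pct"] = np.clip(
        np.round(100 * stats.norm.cdf(-0.9 + 1.1 * _latent(z, es, +1, rng))),
        0, 100).astype(int)

    lam = binary_loading(es, 0.17)
    gamble = _count_from_latent(_latent(z, lam, -1, rng),
                                stats.norm.ppf(0.83), 0.8, 3.0)
    out["gambling_days"] = np.clip(gamble, 0, 30)

    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# Study-2 patience pairs and criterion block
# --------------------------------------------------------------------------

# name, modal-class base rate, sign of the patience loading (+: patient
# respondents more likely positive).  Rates echo a large national survey's
# self-control items.
STUDY2_BINARY_SPECS = [
    ("difficult_run_mile", 0.524, -1), ("not_easy_climb_stairs", 0.604, -1),
    ("overweight", 0.717, -1), ("exercise_light_ever", 0.738, +1),
    ("exercise_vigorous_ever", 0.681, +1), ("exercise_strength_ever", 0.628, +1),
    ("checks_nutrition", 0.514, +1), ("eats_fast_food", 0.646, -1),
    ("drinks_soft_drinks", 0.579, -1), ("health_insurance", 0.810, +1),
    ("flu_vaccine", 0.681, +1), ("sees_dentist", 0.668, +1),
    ("brushes_teeth_2day", 0.741, +1), ("flosses_daily", 0.599, +1),
    ("smoked_100_cigs", 0.575, -1), ("smoking", 0.728, -1),
    ("drinking", 0.527, -1), ("drinking_heavy", 0.859, -1),
    ("cannabis", 0.617, -1), ("cocaine", 0.767, -1),
    ("stimulants", 0.887, -1), ("other_drugs", 0.824, -1),
    ("divorced", 0.536, -1), ("stopped_by_police", 0.824, -1),
    ("convicted", 0.951, -1), ("saving", 0.716, +1),
    ("retirement_account", 0.523, +1), ("missed_bill_payment", 0.787, -1),
    ("cc_debt_any", 0.531, -1), ("cc_maxed_out", 0.887, -1),
    ("debt_to_businesses", 0.796, -1), ("negative_net_worth", 0.885, -1),
]

# name, generator kind, location, scale, sign
STUDY2_CONTINUOUS_SPECS = [
    ("exercise_light_min_y", "lognormal", 9.3, 1.3, +1),
    ("exercise_vigorous_min_y", "lognormal", 9.1, 1.3, +1),
    ("sleep_min_weekday", "normal", 420.0, 80.0, +1),
    ("sleep_min_weekend", "normal", 440.0, 90.0, +1),
    ("drinks_last_month", "lognormal", 2.6, 1.2, -1),
    ("sexual_debut", "normal", 17.5, 2.8, +1),
    ("net_family_income", "sqrtnormal", 230.0, 80.0, +1),
    ("cc_debt_dollars", "lognormal", 8.3, 1.2, -1),
]


def generate_study2_responses(cohort: list[RespondentProfile],
                              config: SimulationConfig,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Patience-pair responses and a 40-column criterion block.

    ``month_amount`` / ``year_amount`` are the smallest extra dollar amounts
    the respondent would demand to wait 1 month / 1 year for a $1000 prize:
    zero (maximal patience) with probability ``zero_inflation``, otherwise a
    rounded lognormal whose log-scale location decreases in ``latent_z`` with
    variance share ``patience_loading``.  The 32 binary and 8 continuous
    criterion columns load on ``latent_z`` with loadings calibrated to
    ``config.effect_size``.
    """
    if not cohort:
        raise InputError("cohort must be nonempty")
    es = config.effect_size
    z = np.array([p.latent_z for p in cohort])
    n = len(cohort)
    out = {"subject_id": [p.subject_id for p in cohort]}

    rho = config.patience_loading
    for item, extra_mu in (("month_amount", 0.0), ("year_amount", np.log(4.0))):
        g = (config.lognormal_mu + extra_mu
             + config.lognormal_sigma * _latent(z, rho, -1, rng))
        amount = np.maximum(np.round(np.exp(g)), 1.0)
        # respondents give round numbers: one significant figure, so the
        # distinct-pair count stays in the hundreds even for large cohorts
        power = 10.0 ** np.floor(np.log10(amount))
        amount = np.round(amount / power) * power
        zero = rng.random(n) < config.zero_inflation
        out[item] = np.where(zero, 0, amount).astype(np.int64)

    for name, base_rate, sign in STUDY2_BINARY_SPECS:
        p_pos = 1.0 - base_rate  # minority class coded 1
        lam = binary_loading(es, p_pos)
        u = _latent(z, lam, sign, rng)
        out[name] = (u >= stats.norm.ppf(1.0 - p_pos)).astype(int)

    for name, kind, loc, scale, sign in STUDY2_CONTINUOUS_SPECS:
        u = _latent(z, es, sign, rng)
        if kind == "lognormal":
            val = np.round(np.exp(loc + scale * u))
        elif kind == "sqrtnormal":
            val = np.round(np.maximum(loc + scale * u, 1.0) ** 2)
        else:
            val = np.round(loc + scale * u)
        out[name] = np.maximum(val, 1.0)

    return pd.DataFrame(out)
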