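"""Administration and scoring of the three time-preference test families.

Each family measures a monthly discount factor (or a rank proxy for it) in a
*near* variant (SS available today) and a *far* variant (a 1-month front-end
delay added to both options):

* **fixed** -- a bank of K forced-choice items ordered by the discount rate at
  which SS and LL are indifferent; scored by the most consistent item rank,
  affinely rescaled.
* **bisection** -- an adaptive forced-choice test driven by the probabilistic
  bisection algorithm: a discretized posterior over the discount factor is
  queried at its median each trial and updated with a fixed response
  reliability p_c; the score is the final posterior median.
* **matching** -- free-response: the subject fills in the LL amount that makes
  the options indifferent; scored by the median of SS/LL ratios.

All scores are oriented so that greater means more patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import AdministrationError, ConfigurationError, InputError

__all__ = [
    "ChoiceItem",
    "FixedItemBank",
    "PosteriorState",
    "TestResult",
    "Trial",
    "KIRBY_MEDIUM_ITEMS",
    "build_fixed_test",
    "run_fixed_test",
    "score_fixed",
    "pba_update",
    "pba_posterior_median",
    "run_bisection_test",
    "run_matching_test",
    "MatchingPrompt",
    "score_matching",
    "trials_to_frame",
]

FRONT_END_DELAY_DAYS = 30


# --------------------------------------------------------------------------
# items and banks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChoiceItem:
    """A forced choice between a smaller-sooner and a larger-later reward."""

    ss_amount: float
    ss_delay_days: int
    ll_amount: float
    ll_delay_days: int
    item_rank: int | None = None
    is_catch: bool = False

    def __post_init__(self):
        if self.ll_delay_days <= self.ss_delay_days:
            raise InputError("LL delay must exceed SS delay")
        if not self.is_catch and self.ll_amount <= self.ss_amount:
            raise InputError("non-catch items need ll_amount > ss_amount")

    @property
    def indifference_rate(self) -> float:
        """Hyperbolic discount rate k at which SS and LL are indifferent."""
        horizon = self.ll_delay_days - self.ss_delay_days
        return (self.ll_amount - self.ss_amount) / (self.ss_amount * horizon)


# Medium-magnitude forced-choice items from the widely used 27-item monetary
# choice questionnaire, ordered by indifference discount rate.  (ss, ll,
# ll_delay_days); ss delay is 0 in the near variant.  Editable: pass your own
# bank to override.
KIRBY_MEDIUM_ITEMS = [
    (54, 55, 117),
    (47, 50, 160),
    (54, 60, 111),
    (49, 60, 89),
    (40, 55, 62),
    (34, 50, 30),
    (27, 50, 21),
    (25, 60, 14),
    (20, 55, 7),
]


@dataclass(frozen=True)
class FixedItemBank:
    """Ordered item bank with ranks 1..K increasing in indifference rate."""

    items: tuple[ChoiceItem, ...]

    def __post_init__(self):
        rates = [it.indifference_rate for it in self.items]
        ranks = [it.item_rank for it in self.items]
        if ranks != list(range(1, len(self.items) + 1)):
            raise ConfigurationError("item_rank must run 1..K in order")
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ConfigurationError(
                "item_rank must be strictly increasing in indifference rate")

    @property
    def k(self) -> int:
        return len(self.items)

    @classmethod
    def default(cls, k: int = 7) -> "FixedItemBank":
        if not (1 <= k <= len(KIRBY_MEDIUM_ITEMS)):
            raise ConfigurationError(
                f"k must lie in [1, {len(KIRBY_MEDIUM_ITEMS)}]")
        items = tuple(
            ChoiceItem(ss_amount=ss, ss_delay_days=0,
                       ll_amount=ll, ll_delay_days=d, item_rank=i + 1)
            for i, (ss, ll, d) in enumerate(KIRBY_MEDIUM_ITEMS[:k]))
        return cls(items)

    @classmethod
    def from_csv(cls, path) -> "FixedItemBank":
        df = pd.read_csv(path).sort_values("rank")
        items = tuple(
            ChoiceItem(ss_amount=r.ss_amount, ss_delay_days=0,
                       ll_amount=r.ll_amount, ll_delay_days=r.ll_delay_days,
                       item_rank=int(r.rank))
            for r in df.itertuples())
        return cls(items)


def build_fixed_test(bank: FixedItemBank, variant: str) -> list[ChoiceItem]:
    """Items for the near or far fixed test.

    The near test presents the bank as-is (SS today); the far test shifts both
    delays by 30 days, leaving amounts and the LL-SS delay gap unchanged.
    """
    if variant == "near":
        return list(bank.items)
    if variant == "far":
        return [replace(it,
                        ss_delay_days=it.ss_delay_days + FRONT_END_DELAY_DAYS,
                        ll_delay_days=it.ll_delay_days + FRONT_END_DELAY_DAYS)
                for it in bank.items]
    raise InputError(f"variant must be 'near' or 'far', got {variant!r}")


# --------------------------------------------------------------------------
# trial log and results
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    index: int
    ss_amount: float
    ll_amount: float
    ss_delay_days: int
    ll_delay_days: int
    response: object  # 'SS'/'LL' for choices, dollar amount for matching
    is_catch: bool = False
    is_error: bool = False  # matching trials with ll < ss


@dataclass
class TestResult:
    """Trial log plus scalar score for one test administration."""

    __test__ = False  # not a pytest test class despite the name

    family: str  # fixed | bisection | matching
    variant: str  # near | far
    score: float
    trials: list[Trial] = field(default_factory=list)
    catch_failures: int = 0

    @property
    def error_trials(self) -> int:
        return sum(t.is_error for t in self.trials)


def trials_to_frame(results: list[TestResult], **extra) -> pd.DataFrame:
    """Flatten trial logs into one tidy frame (CSV-ready)."""
    rows = []
    for res in results:
        for t in res.trials:
            rows.append({**extra, "family": res.family, "variant": res.variant,
                         "trial": t.index, "ss_amount": t.ss_amount,
                         "ll_amount": t.ll_amount,
                         "ss_delay_days": t.ss_delay_days,
                         "ll_delay_days": t.ll_delay_days,
                         "response": t.response, "is_catch": t.is_catch,
                         "is_error": t.is_error})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# fixed-test scoring
# --------------------------------------------------------------------------

def score_fixed(choices, bank: FixedItemBank,
                transform: tuple[float, float] = (2.0, -2.0)) -> float:
    """Most-consistent-rank score for a fixed test.

    Candidate indifference ranks r = 1..K+1 predict LL on exactly the r-1
    highest-rank items (which offer the steepest tradeoffs) and SS elsewhere.
    The subject's rank is the arithmetic mean of the candidates with maximal
    agreement with the observed choices, and the score is ``a * rank + b``
    (default (2, -2), giving a 0..2K scale for K items).
    """
    k = bank.k
    if len(choices) != k:
        raise InputError(f"need one choice per item: expected {k}, "
                         f"got {len(choices)}")
    ll = np.array([c == "LL" for c in choices])
    if not set(np.unique(np.asarray(choices))) <= {"SS", "LL"}:
        raise InputError("choices must be 'SS' or 'LL'")
    consistency = np.empty(k + 1)
    for r in range(1, k + 2):
        predicted_ll = np.arange(1, k + 1) > k - (r - 1)
        consistency[r - 1] = np.sum(predicted_ll == ll)
    best = np.flatnonzero(consistency == consistency.max()) + 1
    rank = float(best.mean())
    a, b = transform
    return a * rank + b


def run_fixed_test(respond, variant: str,
                   bank: FixedItemBank | None = None,
                   transform: tuple[float, float] = (2.0, -2.0)) -> TestResult:
    """Administer a fixed test through a choice callback and score it."""
    if bank is None:
        bank = FixedItemBank.default()
    items = build_fixed_test(bank, variant)
    trials, choices = [], []
    for i, item in enumerate(items):
        try:
            choice = respond(item)
        except Exception as exc:
            raise AdministrationError(f"callback failed at trial {i}: {exc}",
                                      trials) from exc
        choices.append(choice)
        trials.append(Trial(i, item.ss_amount, item.ll_amount,
                            item.ss_delay_days, item.ll_delay_days, choice))
    return TestResult("fixed", variant, score_fixed(choices, bank, transform),
                      trials)


# --------------------------------------------------------------------------
# probabilistic bisection
# --------------------------------------------------------------------------

@dataclass
class PosteriorState:
    """Discretized posterior over the monthly discount factor on [0, 1]."""

    support: np.ndarray
    density: np.ndarray
    n_updates: int = 0

    @classmethod
    def uniform(cls, grid_size: int = 1024) -> "PosteriorState":
        support = np.linspace(0.0, 1.0, grid_size)
        return cls(support, np.full(grid_size, 1.0 / grid_size))

    def normalized(self) -> bool:
        return abs(self.density.sum() - 1.0) < 1e-9


def pba_update(state: PosteriorState, query_d: float, chose_ll: bool,
               p_c: float = 0.75) -> PosteriorState:
    """One probabilistic-bisection update of the posterior.

    Choosing LL at query ratio ``query_d = SS/LL`` signals a discount factor
    above the query point, so the mass above it is rescaled to total ``p_c``
    and the mass at/below to ``1 - p_c`` (and conversely for an SS choice).
    When the query sits at the posterior median this reduces to the classical
    multiply-by-2p_c / 2(1-p_c) update.  If either side carries no mass the
    update is a no-op with a warning.
    """
    if not (0.5 < p_c < 1.0):
        raise ConfigurationError("p_c must lie in (0.5, 1)")
    if not state.normalized():
        raise InputError("posterior state is not normalized")
    above = state.support > query_d
    mass_above = float(state.density[above].sum())
    mass_below = 1.0 - mass_above
    if mass_above <= 0.0 or mass_below <= 0.0:
        warnings.warn("degenerate posterior: all mass on one side of the "
                      "query; update skipped", stacklevel=2)
        return PosteriorState(state.support, state.density.copy(),
                              state.n_updates)
    fav, unfav = (p_c, 1.0 - p_c) if chose_ll else (1.0 - p_c, p_c)
    density = np.where(above, state.density * (fav / mass_above),
                       state.density * (unfav / mass_below))
    density /= density.sum()
    return PosteriorState(state.support, density, state.n_updates + 1)


def pba_posterior_median(state: PosteriorState) -> float:
    """Smallest grid point whose cumulative mass reaches 1/2."""
    if not state.normalized():
        raise InputError("posterior state is not normalized")
    cdf = np.cumsum(state.density)
    return float(state.support[np.argmax(cdf >= 0.5 - 1e-12)])


_BISECTION_DELAYS = {"near": (0, 30), "far": (30, 60)}
CATCH_RATIOS = (0.07, 1.13)


def run_bisection_test(respond, variant: str, n_trials: int = 20,
                       p_c: float = 0.75,
                       rng: np.random.Generator | None = None,
                       grid_size: int = 1024,
                       catch_ratios: tuple = CATCH_RATIOS) -> TestResult:
    """Administer an adaptive bisection test.

    Each scored trial draws LL uniformly from $15..$95 and sets SS to
    ``round(median * LL)`` (at least $1), so the effective query ratio is the
    rounded SS/LL actually shown.  Two catch trials with amount ratios 0.07
    (LL dominant for all but the most impatient) and 1.13 (SS strictly
    dominant) are interleaved at seeded random positions; they never update
    the posterior, and choosing the designated wrong option increments
    ``catch_failures``.  The score is the final posterior median.
    """
    if variant not in _BISECTION_DELAYS:
        raise InputError(f"variant must be 'near' or 'far', got {variant!r}")
    if rng is None:
        rng = np.random.default_rng()
    ss_delay, ll_delay = _BISECTION_DELAYS[variant]
    state = PosteriorState.uniform(grid_size)

    n_total = n_trials + len(catch_ratios)
    slots = rng.permutation(n_total)[:len(catch_ratios)]
    catch_at = dict(zip(slots.tolist(), catch_ratios))

    trials = []
    catch_failures = 0
    for i in range(n_total):
        if i in catch_at:
            ratio = catch_at[i]
            ll = int(rng.integers(15, 96))
            ss = max(1, round(ratio * ll))
            item = ChoiceItem(ss, ss_delay, ll, ll_delay, is_catch=True)
            try:
                choice = respond(item)
            except Exception as exc:
                raise AdministrationError(
                    f"callback failed at trial {i}: {exc}", trials) from exc
            wrong = "SS" if ratio < 1.0 else "LL"
            if choice == wrong:
                catch_failures += 1
            trials.append(Trial(i, ss, ll, ss_delay, ll_delay, choice,
                                is_catch=True))
            continue
        ll = int(rng.integers(15, 96))
        # clamp to a genuine SS/LL tradeoff: at least $1, strictly below LL
        ss = min(max(1, round(pba_posterior_median(state) * ll)), ll - 1)
        item = ChoiceItem(ss, ss_delay, ll, ll_delay)
        try:
            choice = respond(item)
        except Exception as exc:
            raise AdministrationError(
                f"callback failed at trial {i}: {exc}", trials) from exc
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = pba_update(state, ss / ll, choice == "LL", p_c)
        trials.append(Trial(i, ss, ll, ss_delay, ll_delay, choice))

    return TestResult("bisection", variant, pba_posterior_median(state),
                      trials, catch_failures)


# --------------------------------------------------------------------------
# matching
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchingPrompt:
    """Fill-in-the-blank prompt: the LL amount is what the subject supplies."""

    ss_amount: float
    ss_delay_days: int
    ll_delay_days: int


def run_matching_test(respond, variant: str, n_trials: int = 10,
                      rng: np.random.Generator | None = None) -> TestResult:
    """Administer a matching (fill-in-the-blank) test.

    Each trial draws SS uniformly from $1..$95 and asks the callback for the
    LL amount (cent precision) that makes the options indifferent.  Responses
    with ``ll < ss`` are flagged as error trials -- they still enter scoring,
    but feed the exclusion accounting.
    """
    if variant not in _BISECTION_DELAYS:
        raise InputError(f"variant must be 'near' or 'far', got {variant!r}")
    if rng is None:
        rng = np.random.default_rng()
    ss_delay, ll_delay = _BISECTION_DELAYS[variant]
    trials = []
    for i in range(n_trials):
        ss = int(rng.integers(1, 96))
        prompt = MatchingPrompt(ss, ss_delay, ll_delay)
        try:
            ll = float(respond(prompt))
        except Exception as exc:
            raise AdministrationError(
                f"callback failed at trial {i}: {exc}", trials) from exc
        if not np.isfinite(ll) or ll <= 0:
            raise AdministrationError(
                f"nonpositive matching response at trial {i}: {ll}", trials)
        ll = round(ll, 2)
        trials.append(Trial(i, ss, ll, ss_delay, ll_delay, ll,
                            is_error=ll < ss))
    result = TestResult("matching", variant, float("nan"), trials)
    result.score = score_matching(result)
    return result


def score_matching(result: TestResult) -> float:
    """Median of per-trial SS/LL ratios (even counts -> midpoint)."""
    ratios = [t.ss_amount / t.ll_amount for t in result.trials
              if not t.is_catch]
    if not ratios:
        raise InputError("no trials to score")
    return float(np.median(ratios))
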