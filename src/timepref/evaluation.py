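"""Association-versus-prediction engine.

The central contrast: *association* is how well a model fits the cases it
was trained on (R-squared, Efron's R-squared), while *predictive accuracy* is
how well it estimates cases it has never seen (out-of-fold RMSE, proportion
correct, MAE from k-fold cross-validation), judged against a
predictor-free baseline (SD of the outcome, modal-class base rate, or mean
absolute deviation from the median).  Because of overfitting, association is
an optimistic estimate of prediction; the two can diverge sharply.

Also here: reliability as self-prediction (scores predicting later scores of
the same test, with no model to train), cross-validated convergent validity
with range clipping, nonstationarity classification, and robust descriptive
statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import DegenerateOutcomeError, FittingError, InputError

__all__ = [
    "ModelSpec",
    "FittedModel",
    "PredictionAssessment",
    "ReliabilityReport",
    "design_matrix_study1",
    "fit_model",
    "efron_r2",
    "kfold_indices",
    "kfold_predict",
    "assess_prediction",
    "reliability_report",
    "convergent_validity",
    "pvaf",
    "pvaf_from_correlation",
    "classify_nonstationarity",
    "nonstationarity_counts",
    "describe_scores",
]

logger = logging.getLogger(__name__)

_FAMILIES = {"continuous", "binary", "ordinal", "median"}


@dataclass(frozen=True)
class ModelSpec:
    """Dependent-variable family and fitting method.

    continuous -> least squares; binary -> probit maximum likelihood;
    ordinal -> ordinal probit maximum likelihood; median -> quantile (0.5)
    regression.
    """

    dv_family: str

    def __post_init__(self):
        if self.dv_family not in _FAMILIES:
            raise InputError(f"unknown dv_family {self.dv_family!r}")


def design_matrix_study1(near_score, far_score) -> np.ndarray:
    """Four-term design: intercept, near and far main effects, interaction."""
    near = np.atleast_1d(np.asarray(near_score, dtype=float))
    far = np.atleast_1d(np.asarray(far_score, dtype=float))
    if not (np.isfinite(near).all() and np.isfinite(far).all()):
        raise InputError("scores must be finite")
    return np.column_stack([np.ones_like(near), near, far, near * far])


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------

@dataclass
class FittedModel:
    """Coefficients plus a predict function on new design rows.

    ``predict`` returns expected values (continuous), class-1 probabilities
    (binary), a category-probability matrix (ordinal), or conditional
    medians (median loss).
    """

    spec: ModelSpec
    params: np.ndarray
    _predict: object
    categories: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        return self._predict(np.asarray(X, dtype=float))


def _nonconstant_columns(X):
    return np.flatnonzero(np.ptp(X, axis=0) > 0)


def _check_design(X, y, spec):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise InputError("X must be 2-D and aligned with y")
    if len(y) <= X.shape[1]:
        raise InputError("need more cases than design terms")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FittingError("singular design matrix")
    if spec.dv_family == "binary" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise InputError("binary y must be coded 0/1")
    return X, y


def fit_model(spec: ModelSpec, X, y) -> FittedModel:
    """Fit the family's model and return coefficients + predict function."""
    X, y = _check_design(X, y, spec)

    if spec.dv_family == "continuous":
        res = sm.OLS(y, X).fit()
        return FittedModel(spec, res.params, lambda Xn: Xn @ res.params)

    if spec.dv_family == "median":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.QuantReg(y, X).fit(q=0.5, max_iter=2000)
        return FittedModel(spec, res.params, lambda Xn: Xn @ res.params)

    if spec.dv_family == "binary":
        if len(np.unique(y)) < 2:
            raise FittingError("constant binary outcome")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = sm.Probit(y, X).fit(disp=0, maxiter=200)
                except np.linalg.LinAlgError:
                    # singular Hessian mid-Newton: retry gradient-only
                    res = sm.Probit(y, X).fit(method="bfgs", disp=0,
                                              maxiter=500)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise FittingError(f"probit fit failed: {exc}") from exc
        if not np.isfinite(res.params).all() or \
                np.abs(res.params).max() > 1e6:
            raise FittingError("probit fit diverged (perfect separation?)")
        p_fit = stats.norm.cdf(X @ res.params)
        if np.all((p_fit < 1e-6) | (p_fit > 1 - 1e-6)) and \
                np.all((p_fit > 0.5) == (y == 1)):
            raise FittingError("perfect separation in probit fit")
        beta = res.params
        return FittedModel(spec, beta,
                           lambda Xn: stats.norm.cdf(Xn @ beta))

    # ordinal probit: thresholds absorb the intercept, so constant columns
    # are dropped from the design
    cats = np.unique(y)
    if len(cats) < 2:
        raise FittingError("constant ordinal outcome")
    keep = _nonconstant_columns(X)
    if len(keep) == 0:
        raise FittingError("ordinal design has no varying predictors")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(y, X[:, keep], distr="probit")
            res = model.fit(method="bfgs", disp=0, maxiter=500)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise FittingError(f"ordinal probit fit failed: {exc}") from exc
    if not np.isfinite(res.params).all():
        raise FittingError("ordinal probit fit diverged")

    def predict(Xn):
        return np.asarray(model.predict(res.params, exog=Xn[:, keep]))

    return FittedModel(spec, res.params, predict, categories=cats)


def _intercept_only(spec: ModelSpec, y_train, categories=None):
    """Fallback fit used when a training fold is degenerate."""
    y_train = np.asarray(y_train, dtype=float)
    if spec.dv_family in {"continuous", "binary"}:
        const = float(np.mean(y_train))
        return lambda Xn: np.full(len(Xn), const)
    if spec.dv_family == "median":
        const = float(np.median(y_train))
        return lambda Xn: np.full(len(Xn), const)
    cats = np.asarray(categories)
    probs = np.array([(y_train == c).mean() for c in cats])
    return lambda Xn: np.tile(probs, (len(Xn), 1))


# --------------------------------------------------------------------------
# fit statistics
# --------------------------------------------------------------------------

def efron_r2(y, p_hat) -> float:
    """Efron's pseudo R-squared: 1 - sum((y - p)^2) / sum((y - ybar)^2)."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p_hat, dtype=float)
    if len(y) != len(p):
        raise InputError("y and p_hat must be aligned")
    if np.any((p < 0) | (p > 1)):
        raise InputError("p_hat must lie in [0, 1]")
    denom = np.sum((y - y.mean()) ** 2)
    if denom == 0:
        raise DegenerateOutcomeError("Efron's R^2 undefined for constant y")
    return float(1.0 - np.sum((y - p) ** 2) / denom)


def pvaf(target, predictions) -> float:
    """Proportion of variance accounted for: 1 - MSE / Var(target).

    Population (divide-by-n) variance, so a perfect prediction gives exactly
    1.  May be negative for predictions worse than the target mean.
    """
    t = np.asarray(target, dtype=float)
    p = np.asarray(predictions, dtype=float)
    var = np.var(t)
    if var == 0:
        raise DegenerateOutcomeError("PVAF undefined for zero-variance target")
    return float(1.0 - np.mean((t - p) ** 2) / var)


def pvaf_from_correlation(r: float) -> float:
    """PVAF implied by a correlation coefficient (its square)."""
    return float(r) ** 2


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def kfold_indices(n: int, k: int, seed) -> list[np.ndarray]:
    """Seeded unstratified balanced partition into k folds (sizes differ <=1)."""
    if k < 2:
        raise InputError("k_folds must be >= 2")
    if n < k:
        raise InputError("need n >= k")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def kfold_predict(spec: ModelSpec, X, y, k: int = 10, seed=0) -> np.ndarray:
    """Out-of-fold predictions: each case predicted exactly once.

    Degenerate training folds (constant outcome) and fit failures fall back
    to an intercept-only model and are logged.
    """
    X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=float)
    folds = kfold_indices(len(y), k, seed)
    categories = np.unique(y) if spec.dv_family == "ordinal" else None
    if spec.dv_family == "ordinal":
        preds = np.empty((len(y), len(categories)))
    else:
        preds = np.empty(len(y))
    for fold in folds:
        train = np.setdiff1d(np.arange(len(y)), fold)
        Xtr, ytr = X[train], y[train]
        try:
            if spec.dv_family == "ordinal" and \
                    len(np.unique(ytr)) < len(categories):
                raise FittingError("training fold missing a category")
            fitted = fit_model(spec, Xtr, ytr)
            if spec.dv_family == "ordinal":
                # align probability columns with the global category set
                def predict(Xn, fitted=fitted):
                    p = np.zeros((len(Xn), len(categories)))
                    raw = fitted.predict(Xn)
                    idx = np.searchsorted(categories, fitted.categories)
                    p[:, idx] = raw
                    return p
            else:
                predict = fitted.predict
        except (FittingError, InputError) as exc:
            logger.info("fold fit degenerate (%s); intercept-only fallback",
                        exc)
            predict = _intercept_only(spec, ytr, categories)
        preds[fold] = predict(X[fold])
    return preds


# --------------------------------------------------------------------------
# paired association / prediction assessment
# --------------------------------------------------------------------------

@dataclass
class PredictionAssessment:
    """In-sample association and out-of-fold predictive accuracy, with the
    predictor-free baseline they should be judged against."""

    dv_family: str
    association: float
    association_metric: str
    predictive: float
    predictive_metric: str
    baseline: float
    baseline_metric: str
    n: int
    k_folds: int
    seed: object

    def beats_baseline(self) -> bool:
        """Did out-of-fold prediction beat the predictor-free baseline?"""
        if self.predictive_metric in {"rmse", "mae"}:
            return self.predictive < self.baseline
        return self.predictive > self.baseline


def _ordinal_expected_index(probs, categories):
    idx = np.arange(len(categories))
    return probs @ idx


def _point_class(preds, spec, categories=None):
    if spec.dv_family == "binary":
        return (np.asarray(preds) > 0.5).astype(float)
    return np.asarray(categories)[np.argmax(preds, axis=1)]


def assess_prediction(spec: ModelSpec, X, y, k: int = 10,
                      seed=0) -> PredictionAssessment:
    """Fit in-sample and cross-validate, returning the paired metrics.

    continuous: association R^2, predictive RMSE, baseline SD.
    binary/ordinal: association Efron's R^2 (expected-category version for
    ordinal), predictive proportion correct (argmax class), baseline
    modal-class base rate.
    median: association in-sample MAE, predictive out-of-fold MAE, baseline
    mean absolute deviation from the median.
    """
    X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=float)
    fitted = fit_model(spec, X, y)
    oof = kfold_predict(spec, X, y, k=k, seed=seed)
    n = len(y)

    if spec.dv_family == "continuous":
        resid = y - fitted.predict(X)
        tss = np.sum((y - y.mean()) ** 2)
        association = float(1.0 - np.sum(resid ** 2) / tss)
        predictive = float(np.sqrt(np.mean((y - oof) ** 2)))
        baseline = float(np.std(y))
        metrics = ("r2", "rmse", "sd")
    elif spec.dv_family == "median":
        association = float(np.mean(np.abs(y - fitted.predict(X))))
        predictive = float(np.mean(np.abs(y - oof)))
        baseline = float(np.mean(np.abs(y - np.median(y))))
        metrics = ("mae", "mae", "mad_from_median")
    elif spec.dv_family == "binary":
        association = efron_r2(y, fitted.predict(X))
        predictive = float(np.mean(_point_class(oof, spec) == y))
        baseline = float(max(np.mean(y), 1.0 - np.mean(y)))
        metrics = ("efron_r2", "proportion_correct", "base_rate")
    else:  # ordinal
        cats = fitted.categories
        probs = fitted.predict(X)
        y_idx = np.searchsorted(cats, y).astype(float)
        e_idx = _ordinal_expected_index(probs, cats)
        denom = np.sum((y_idx - y_idx.mean()) ** 2)
        if denom == 0:
            raise DegenerateOutcomeError("constant ordinal outcome")
        association = float(1.0 - np.sum((y_idx - e_idx) ** 2) / denom)
        predictive = float(np.mean(_point_class(oof, spec, cats) == y))
        baseline = float(max((y == c).mean() for c in cats))
        metrics = ("efron_r2_expected_index", "proportion_correct",
                   "base_rate")

    return PredictionAssessment(spec.dv_family, association, metrics[0],
                                predictive, metrics[1], baseline, metrics[2],
                                n, k, seed)


# --------------------------------------------------------------------------
# reliability as self-prediction
# --------------------------------------------------------------------------

@dataclass
class ReliabilityReport:
    """How well raw earlier scores predict later scores of the same test."""

    pvaf: float
    abs_err_median: float
    abs_err_p90: float
    abs_err_p95: float
    bias: float
    kendall_tau: float
    pearson_r: float
    n: int


def reliability_report(predictor_scores, target_scores) -> ReliabilityReport:
    """Self-prediction accuracy of unaltered scores (no model, no CV).

    ``bias`` is mean(target - predictor); PVAF uses the population variance
    of the target, so identical scores give exactly 1.  A zero-variance
    target leaves PVAF as NaN but still reports the error quantiles.
    """
    p = np.asarray(predictor_scores, dtype=float)
    t = np.asarray(target_scores, dtype=float)
    if len(p) != len(t) or len(p) == 0:
        raise InputError("need paired, nonempty score vectors")
    err = np.abs(t - p)
    var = np.var(t)
    if var == 0:
        warnings.warn("zero-variance target: PVAF undefined", stacklevel=2)
        pv = float("nan")
    else:
        pv = float(1.0 - np.mean((t - p) ** 2) / var)
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        tau = r = float("nan")
    else:
        tau = float(stats.kendalltau(p, t).statistic)
        r = float(stats.pearsonr(p, t).statistic)
    return ReliabilityReport(
        pvaf=pv,
        abs_err_median=float(np.percentile(err, 50)),
        abs_err_p90=float(np.percentile(err, 90)),
        abs_err_p95=float(np.percentile(err, 95)),
        bias=float(np.mean(t - p)),
        kendall_tau=tau,
        pearson_r=r,
        n=len(p),
    )


def convergent_validity(scores_a, scores_b, legal_range, k: int = 10,
                        seed=0) -> float:
    """PVAF of one test's scores predicting another's, out-of-fold.

    Tenfold cross-validated simple linear regression of b on a, with
    predictions clipped to the legal range of the DV.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b):
        raise InputError("scores must be paired")
    X = np.column_stack([np.ones_like(a), a])
    oof = kfold_predict(ModelSpec("continuous"), X, b, k=k, seed=seed)
    lo, hi = legal_range
    return pvaf(b, np.clip(oof, lo, hi))


# --------------------------------------------------------------------------
# nonstationarity and descriptives
# --------------------------------------------------------------------------

def classify_nonstationarity(near_score: float, far_score: float) -> str:
    """Compare near and far scores of one subject on the same scale.

    A greater far score means the subject plans to be more patient in the
    future (classical nonstationarity); equal scores mean perfect
    stationarity.
    """
    if far_score > near_score:
        return "more_patient_later"
    if far_score < near_score:
        return "less_patient_later"
    return "stationary"


def nonstationarity_counts(near_scores, far_scores) -> dict[str, int]:
    """Counts of each nonstationarity category; always sums to n."""
    near = np.asarray(near_scores, dtype=float)
    far = np.asarray(far_scores, dtype=float)
    return {
        "less_patient_later": int(np.sum(far < near)),
        "stationary": int(np.sum(far == near)),
        "more_patient_later": int(np.sum(far > near)),
    }


def describe_scores(scores, mad: str = "median") -> dict[str, float]:
    """Quartiles (linear interpolation) and a robust spread measure.

    ``mad='median'`` gives the median absolute deviation from the median;
    ``mad='mean'`` gives the mean absolute deviation from the median.
    """
    x = np.asarray(scores, dtype=float)
    if len(x) == 0:
        raise InputError("scores must be nonempty")
    med = float(np.median(x))
    dev = np.abs(x - med)
    if mad == "median":
        spread = float(np.median(dev))
    elif mad == "mean":
        spread = float(np.mean(dev))
    else:
        raise InputError("mad must be 'median' or 'mean'")
    return {
        "Q1": float(np.percentile(x, 25)),
        "median": med,
        "Q3": float(np.percentile(x, 75)),
        "MAD": spread,
    }
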