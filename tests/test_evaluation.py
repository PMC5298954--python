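"""The association-vs-prediction engine, checked against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from timepref import (DegenerateOutcomeError, FittingError, InputError,
                      ModelSpec, assess_prediction, classify_nonstationarity,
                      convergent_validity, describe_scores,
                      design_matrix_study1, efron_r2, fit_model,
                      kfold_predict, nonstationarity_counts, pvaf,
                      pvaf_from_correlation, reliability_report)
from timepref.evaluation import kfold_indices


class TestDesignMatrix:
    @pytest.mark.parametrize("near,far,row", [
        (2, 3, [1, 2, 3, 6]),
        (0, 0, [1, 0, 0, 0]),
        (0.5, 0.8, [1, 0.5, 0.8, 0.4]),
    ])
    def test_four_terms(self, near, far, row):
        np.testing.assert_allclose(design_matrix_study1(near, far)[0], row)

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            design_matrix_study1([np.nan], [1.0])


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------

def probit_grid_oracle(x, y, span=4.0, steps=81, rounds=4):
    """Brute-force 2-D likelihood grid search for intercept-slope probit."""
    center = np.zeros(2)
    width = span
    for _ in range(rounds):
        b0 = np.linspace(center[0] - width, center[0] + width, steps)
        b1 = np.linspace(center[1] - width, center[1] + width, steps)
        B0, B1 = np.meshgrid(b0, b1, indexing="ij")
        eta = B0[..., None] + B1[..., None] * x[None, None, :]
        p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
        ll = np.sum(np.where(y[None, None, :] == 1, np.log(p),
                             np.log(1 - p)), axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        center = np.array([b0[i], b1[j]])
        width = 2 * width / (steps - 1) * 2
    return center


PROBIT_FIXTURES = [
    (np.array([-1.2, -0.7, -0.3, 0.1, 0.4, 0.9, 1.3, -0.5, 0.2, 0.8,
               -1.0, 0.6, 1.1, -0.2, 0.3, -0.8, 0.7, 0.0, 1.4, -1.3]),
     np.array([0, 0, 0, 1, 0, 1, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0, 1, 0])),
    (np.array([0.5, 1.5, 2.5, 0.2, 1.8, 2.2, 0.9, 1.1, 2.9, 0.4,
               1.6, 2.1, 0.7, 1.3, 2.6, 0.1, 1.9, 2.4, 0.8, 1.2]),
     np.array([0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 1, 0])),
]


class TestFitModel:
    @pytest.mark.parametrize("x,y", PROBIT_FIXTURES)
    def test_probit_matches_likelihood_grid(self, x, y):
        X = np.column_stack([np.ones_like(x), x])
        fitted = fit_model(ModelSpec("binary"), X, y.astype(float))
        oracle = probit_grid_oracle(x, y)
        np.testing.assert_allclose(fitted.params, oracle, atol=1e-3)

    def test_least_squares_exact_line(self):
        x = np.arange(10, dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        fitted = fit_model(ModelSpec("continuous"), X, 2 * x)
        np.testing.assert_allclose(fitted.params, [0.0, 2.0], atol=1e-10)

    def test_median_regression_ignores_gross_outlier(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 60)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.01, 60)
        X = np.column_stack([np.ones_like(x), x])
        clean = fit_model(ModelSpec("median"), X, y).params
        y_out = y.copy()
        y_out[0] += 1000.0
        dirty = fit_model(ModelSpec("median"), X, y_out).params
        np.testing.assert_allclose(clean, dirty, atol=0.02)

    def test_median_regression_matches_linear_program(self):
        # independent oracle: least-absolute-deviations as an LP in
        # (beta, residual+, residual-)
        from scipy.optimize import linprog
        rng = np.random.default_rng(14)
        x = rng.uniform(0, 1, 40)
        y = 0.5 + 1.5 * x + rng.normal(0, 0.3, 40)
        X = np.column_stack([np.ones_like(x), x])
        n, p = X.shape
        c = np.concatenate([np.zeros(2 * p), np.ones(2 * n)])
        A_eq = np.hstack([X, -X, np.eye(n), -np.eye(n)])
        res = linprog(c, A_eq=A_eq, b_eq=y, method="highs")
        beta_lp = res.x[:p] - res.x[p:2 * p]
        fitted = fit_model(ModelSpec("median"), X, y)
        mae_lp = np.mean(np.abs(y - X @ beta_lp))
        mae_fit = np.mean(np.abs(y - fitted.predict(X)))
        assert mae_fit == pytest.approx(mae_lp, abs=1e-6)

    def test_perfect_separation_raises(self):
        x = np.array([-2., -1.5, -1., 1., 1.5, 2.])
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones_like(x), x])
        with pytest.raises(FittingError):
            fit_model(ModelSpec("binary"), X, y)

    def test_singular_design_raises(self):
        x = np.ones(10)
        X = np.column_stack([np.ones_like(x), x])
        with pytest.raises(FittingError):
            fit_model(ModelSpec("continuous"), X, np.arange(10.0))

    def test_ordinal_probit_recovers_threshold_order(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 400)
        latent = 1.5 * x + rng.normal(0, 1, 400)
        y = np.digitize(latent, [-1.0, 1.0]).astype(float)
        X = np.column_stack([np.ones_like(x), x])
        fitted = fit_model(ModelSpec("ordinal"), X, y)
        probs = fitted.predict(X)
        assert probs.shape == (400, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-8)
        # higher x shifts mass to higher categories
        hi, lo = x > 1, x < -1
        assert probs[hi, 2].mean() > probs[lo, 2].mean() + 0.3


class TestEfronR2:
    def test_perfect(self):
        assert efron_r2([0, 1, 1], [0, 1, 1]) == 1.0

    def test_base_rate_predictions_give_zero(self):
        y = np.array([0, 0, 1, 1.0])
        assert efron_r2(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_arithmetic_example(self):
        assert efron_r2([0, 1, 1, 0], [0.25, 0.75, 0.75, 0.25]) == \
            pytest.approx(0.75)

    def test_constant_y_signaled(self):
        with pytest.raises(DegenerateOutcomeError):
            efron_r2([1, 1, 1], [0.5, 0.5, 0.5])


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

class TestKfold:
    def test_fold_sizes_balanced(self):
        folds = kfold_indices(23, 10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [2] * 7 + [3] * 3
        assert sorted(np.concatenate(folds)) == list(range(23))

    def test_exact_linear_relation_survives_any_split(self):
        x = np.linspace(0, 1, 50)
        X = np.column_stack([np.ones_like(x), x])
        oof = kfold_predict(ModelSpec("continuous"), X, 2 * x, k=10, seed=3)
        assert np.sqrt(np.mean((oof - 2 * x) ** 2)) < 1e-8

    def test_null_predictors_cannot_beat_sd(self):
        # when y is independent of X, out-of-fold RMSE averages at or above
        # the outcome's spread: the overfitting penalty has no signal to
        # recover
        rng = np.random.default_rng(7)
        excess = []
        for _ in range(200):
            x = rng.normal(0, 1, 40)
            y = rng.normal(0, 1, 40)
            X = np.column_stack([np.ones_like(x), x])
            oof = kfold_predict(ModelSpec("continuous"), X, y, k=10,
                                seed=int(rng.integers(2 ** 31)))
            excess.append(np.sqrt(np.mean((y - oof) ** 2)) - np.std(y))
        assert np.mean(excess) >= 0

    def test_gap_to_in_sample_shrinks_with_n(self):
        rng = np.random.default_rng(11)
        gaps = {}
        for n in (100, 1000):
            x = rng.normal(0, 1, n)
            y = 1 + 2 * x + rng.normal(0, 1, n)
            X = np.column_stack([np.ones_like(x), x])
            fitted = fit_model(ModelSpec("continuous"), X, y)
            in_rmse = np.sqrt(np.mean((y - fitted.predict(X)) ** 2))
            oof = kfold_predict(ModelSpec("continuous"), X, y, k=10, seed=5)
            oof_rmse = np.sqrt(np.mean((y - oof) ** 2))
            gaps[n] = oof_rmse - in_rmse
        assert gaps[1000] < gaps[100]

    def test_degenerate_fold_falls_back_to_intercept(self, caplog):
        # one positive case: its training fold may go single-class; the CV
        # must complete with the intercept-only fallback
        y = np.zeros(20)
        y[0] = 1.0
        x = np.arange(20, dtype=float)
        X = np.column_stack([np.ones(20), x])
        oof = kfold_predict(ModelSpec("binary"), X, y, k=10, seed=1)
        assert np.isfinite(oof).all()


class TestAssessPrediction:
    def test_intercept_only_binary_equals_base_rate(self):
        rng = np.random.default_rng(2)
        y = (rng.random(80) < 0.3).astype(float)
        X = np.ones((80, 1))
        a = assess_prediction(ModelSpec("binary"), X, y, k=10, seed=4)
        assert a.predictive == pytest.approx(a.baseline)

    def test_intercept_only_continuous_rmse_is_sd(self):
        rng = np.random.default_rng(3)
        y = rng.normal(5, 2, 60)
        X = np.ones((60, 1))
        a = assess_prediction(ModelSpec("continuous"), X, y, k=10, seed=4)
        # in-sample association is zero; baseline is the population SD
        assert a.association == pytest.approx(0.0, abs=1e-12)
        assert a.baseline == pytest.approx(np.std(y))

    def test_median_family_metrics(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 100)
        y = 2 * x + rng.normal(0, 0.1, 100)
        X = np.column_stack([np.ones_like(x), x])
        a = assess_prediction(ModelSpec("median"), X, y, k=10, seed=6)
        assert a.predictive_metric == "mae"
        assert a.baseline == pytest.approx(np.mean(np.abs(y - np.median(y))))
        assert a.beats_baseline()


def test_association_exceeds_prediction_under_null():
    """Over repeated null datasets, mean in-sample fit beats mean
    out-of-fold fit: the definition of overfitting."""
    rng = np.random.default_rng(8)
    assoc, pred = [], []
    for _ in range(500):
        x = rng.normal(0, 1, 60)
        y = rng.normal(0, 1, 60)
        X = np.column_stack([np.ones_like(x), x])
        fitted = fit_model(ModelSpec("continuous"), X, y)
        r2 = 1 - np.sum((y - fitted.predict(X)) ** 2) / \
            np.sum((y - y.mean()) ** 2)
        oof = kfold_predict(ModelSpec("continuous"), X, y, k=10,
                            seed=int(rng.integers(2 ** 31)))
        assoc.append(r2)
        pred.append(pvaf(y, oof))
    assert np.mean(assoc) > np.mean(pred)
    assert np.mean(assoc) > 0 > np.mean(pred)


# --------------------------------------------------------------------------
# reliability and convergent validity
# --------------------------------------------------------------------------

class TestReliability:
    def test_identity(self):
        s = np.array([0.2, 0.5, 0.9, 0.4])
        rep = reliability_report(s, s)
        assert rep.pvaf == 1.0
        assert rep.bias == 0.0
        assert rep.abs_err_median == rep.abs_err_p95 == 0.0
        assert rep.kendall_tau == 1.0
        assert rep.pearson_r == pytest.approx(1.0)

    def test_constant_shift(self):
        s = np.array([0.2, 0.5, 0.9, 0.4])
        t = s + 0.1
        rep = reliability_report(s, t)
        assert rep.bias == pytest.approx(0.1)
        assert rep.abs_err_median == pytest.approx(0.1)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.pvaf == pytest.approx(1 - 0.01 / np.var(t))

    def test_quantiles_nondecreasing(self, rng):
        p = rng.normal(0, 1, 100)
        t = p + rng.normal(0, 0.5, 100)
        rep = reliability_report(p, t)
        assert rep.abs_err_median <= rep.abs_err_p90 <= rep.abs_err_p95

    def test_permuted_scores_average_nonpositive_pvaf(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0, 1, 50)
        vals = [reliability_report(rng.permutation(base), base).pvaf
                for _ in range(500)]
        assert np.mean(vals) <= 0

    def test_zero_variance_target_warns(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            rep = reliability_report([1, 2, 3], [5, 5, 5])
        assert np.isnan(rep.pvaf)
        assert rep.bias == pytest.approx(3.0)


class TestConvergentValidity:
    def test_identical_scores(self, rng):
        a = rng.uniform(0, 1, 60)
        assert convergent_validity(a, a, (0, 1), seed=1) >= 0.99

    def test_independent_scores_average_nonpositive(self):
        rng = np.random.default_rng(10)
        vals = [convergent_validity(rng.uniform(0, 1, 40),
                                    rng.uniform(0, 1, 40), (0, 1),
                                    seed=int(rng.integers(2 ** 31)))
                for _ in range(200)]
        assert np.mean(vals) <= 0

    def test_predictions_clipped_to_legal_range(self, rng):
        a = np.linspace(0, 1, 40)
        b = 2 * a  # linear map pushing predictions outside [0, 1]
        oof_pvaf_clipped = convergent_validity(b, a, (0, 0.4), seed=2)
        # a perfect linear relation, but clipping at 0.4 caps accuracy
        assert oof_pvaf_clipped < 0.99


def test_pvaf_from_correlation_examples():
    assert pvaf_from_correlation(0.75) == pytest.approx(0.5625)
    assert pvaf_from_correlation(0.33) == pytest.approx(0.1089)


# --------------------------------------------------------------------------
# Kendall tau oracle
# --------------------------------------------------------------------------

def kendall_tau_b_oracle(x, y):
    """O(n^2) pair-counting tau-b with tie corrections."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - (tx + conc + disc) + conc + disc) *
                    (n0 - (ty + conc + disc) + conc + disc))
    # simplify: n1 = ties in x total pairs, n2 = ties in y total pairs
    n1 = tx
    n2 = ty
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    return (conc - disc) / denom


def test_kendall_tau_matches_pair_counting_oracle():
    rng = np.random.default_rng(13)
    for _ in range(100):
        n = int(rng.integers(5, 30))
        x = rng.integers(0, 6, n).astype(float)  # plenty of ties
        y = rng.integers(0, 6, n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        expected = kendall_tau_b_oracle(x, y)
        got = stats.kendalltau(x, y).statistic
        assert got == pytest.approx(expected, abs=1e-12)


# --------------------------------------------------------------------------
# nonstationarity and descriptives
# --------------------------------------------------------------------------

class TestNonstationarity:
    @pytest.mark.parametrize("near,far,label", [
        (0.7, 0.8, "more_patient_later"),
        (0.7, 0.7, "stationary"),
        (0.8, 0.7, "less_patient_later"),
    ])
    def test_classification(self, near, far, label):
        assert classify_nonstationarity(near, far) == label

    def test_counts_partition(self, rng):
        near = rng.uniform(0, 1, 200)
        far = np.where(rng.random(200) < 0.3, near, rng.uniform(0, 1, 200))
        counts = nonstationarity_counts(near, far)
        assert sum(counts.values()) == 200


class TestDescribeScores:
    def test_integers_one_to_seven(self):
        d = describe_scores(range(1, 8))
        assert d["median"] == 4
        assert d["MAD"] == 2  # deviations {3,2,1,0,1,2,3}

    def test_constant_vector(self):
        assert describe_scores([5, 5, 5])["MAD"] == 0

    def test_two_point_interpolation(self):
        d = describe_scores([0, 10])
        assert d["median"] == 5
        assert d["Q1"] == 2.5  # linear interpolation
        assert d["Q3"] == 7.5

    def test_mean_absolute_deviation_option(self):
        d = describe_scores([0, 0, 12], mad="mean")
        assert d["MAD"] == pytest.approx(4.0)
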