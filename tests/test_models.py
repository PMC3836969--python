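import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from conftest import random_psd_matrix
from dtikit.core_io import EntityRegistry, SimilarityMatrix
from dtikit.evaluation import roc_auc
from dtikit.models import (
    KL1LRFeatures,
    KL1LRModel,
    SVMSpec,
    build_features,
    fit_kl1lr,
    fit_svm,
    kkt_residual,
    penalized_objective_value,
    predict_kl1lr,
)


def kernel_from(values):
    values = np.asarray(values, dtype=float)
    return SimilarityMatrix(
        EntityRegistry(tuple(f"d{i}" for i in range(len(values)))), values
    )


def logistic_mle_oracle(x, y01):
    """Unpenalized logistic fit by a generic convex optimizer (BFGS)."""

    def nll(theta):
        z = theta[0] + x @ theta[1:]
        return np.sum(np.logaddexp(0.0, z) - y01 * z)

    res = minimize(nll, np.zeros(x.shape[1] + 1), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    return res.x


def random_features(rng, n=50, m=1):
    x = rng.normal(size=(n, 2 * m)) * 0.5 + 0.5
    beta = rng.normal(size=2 * m)
    y = (rng.random(n) < expit(x @ beta)).astype(int)
    if y.min() == y.max():  # ensure both classes
        y[0], y[1] = 0, 1
    return KL1LRFeatures(x[:, 0::2], x[:, 1::2], labels=y)


class TestBuildFeatures:
    def test_identity_kernel_gives_zero_means(self):
        k = kernel_from(np.eye(4))
        y = np.array([1, 1, 0, 0])
        f = build_features([k], y, np.arange(4))
        np.testing.assert_array_equal(f.xplus, 0.0)
        np.testing.assert_array_equal(f.xminus, 0.0)

    def test_constant_kernel_gives_constant_features(self):
        k = kernel_from(np.full((5, 5), 0.3))
        y = np.array([1, 1, 0, 0, 1])
        f = build_features([k], y, np.arange(5))
        np.testing.assert_allclose(f.xplus, 0.3)
        np.testing.assert_allclose(f.xminus, 0.3)

    def test_three_drug_example_by_hand(self):
        k = kernel_from([[1.0, 0.8, 0.2], [0.8, 1.0, 0.5], [0.2, 0.5, 1.0]])
        y = np.array([1, 1, 0])
        f = build_features([k], y, np.arange(3), np.array([0]))
        assert f.xplus[0, 0] == pytest.approx(0.8)  # only co-positive is drug 2
        assert f.xminus[0, 0] == pytest.approx(0.2)

    def test_heldout_features_exclude_heldout_from_reference(self):
        k = kernel_from([[1.0, 0.8, 0.2, 0.1], [0.8, 1, 0.5, 0.3],
                         [0.2, 0.5, 1, 0.6], [0.1, 0.3, 0.6, 1]])
        y = np.array([1, 1, 0, 0])
        f = build_features([k], y, np.array([0, 1, 2]), np.array([3]))
        # heldout drug 3: positives among train = {0,1}, negatives = {2}
        assert f.xplus[0, 0] == pytest.approx((0.1 + 0.3) / 2)
        assert f.xminus[0, 0] == pytest.approx(0.6)

    def test_invariant_to_training_order(self):
        rng = np.random.default_rng(0)
        k = random_psd_matrix(rng, 10)
        y = np.array([1, 0, 1, 0, 1, 0, 0, 1, 0, 0])
        train = np.arange(8)
        f1 = build_features([k], y, train, np.array([8, 9]))
        f2 = build_features([k], y, rng.permutation(train), np.array([8, 9]))
        np.testing.assert_allclose(f1.xplus, f2.xplus)
        np.testing.assert_allclose(f1.xminus, f2.xminus)

    def test_single_class_training_rejected(self):
        k = kernel_from(np.eye(3))
        with pytest.raises(ValueError, match="positive"):
            build_features([k], np.array([1, 1, 1]), np.arange(3))


class TestFitKL1LR:
    def test_huge_lambda_returns_null_model(self):
        rng = np.random.default_rng(1)
        f = random_features(rng, n=60)
        prevalence = (f.labels == 1).mean()
        model = fit_kl1lr(f, lam=1e6 * f.n)
        np.testing.assert_allclose(model.coefficients, 0.0)
        assert model.intercept == pytest.approx(
            np.log(prevalence / (1 - prevalence)), abs=1e-6
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_lambda_zero_matches_generic_optimizer(self, seed):
        rng = np.random.default_rng(seed)
        f = random_features(rng, n=50, m=1)
        model = fit_kl1lr(f, lam=0.0)
        oracle = logistic_mle_oracle(f.design, (f.labels == 1).astype(float))
        np.testing.assert_allclose(
            np.concatenate(([model.intercept], model.coefficients)), oracle, atol=1e-4
        )

    def test_kkt_residual_below_contract(self):
        rng = np.random.default_rng(7)
        f = random_features(rng, n=80, m=2)
        for lam in np.geomspace(0.01, 0.3, 13):
            model = fit_kl1lr(f, lam=lam)
            assert model.kkt_residual <= 1e-6

    def test_planted_signal_selects_informative_kernel(self):
        # y depends only on kernel 1's x+; noise kernel coefficients shrink to 0
        rng = np.random.default_rng(3)
        n = 200
        xp1 = rng.random(n)
        y = (rng.random(n) < expit(8.0 * (xp1 - 0.5))).astype(int)
        f = KL1LRFeatures(
            np.column_stack([xp1, rng.random(n)]),
            np.column_stack([rng.random(n), rng.random(n)]),
            labels=y,
        )
        model = fit_kl1lr(f, lam=8.0)
        assert model.coefficients[0] > 0  # beta+ of the signal kernel
        assert np.all(model.coefficients[2:] == 0.0)  # noise kernel zeroed

    def test_objective_not_worse_than_null_and_matches_independent_eval(self):
        rng = np.random.default_rng(12)
        f = random_features(rng, n=70, m=2)
        lam = 0.1
        model = fit_kl1lr(f, lam=lam)
        val = penalized_objective_value(model, f)
        null = KL1LRModel(
            np.log(f.labels.mean() / (1 - f.labels.mean())), np.zeros(2 * f.m), lam
        )
        assert val <= penalized_objective_value(null, f) + 1e-10
        # independent evaluation of the penalized objective
        y01 = (f.labels == 1).astype(float)
        z = model.intercept + f.design @ model.coefficients
        manual = np.sum(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - y01 * z)
        manual += lam * np.abs(model.coefficients).sum()
        assert val == pytest.approx(manual, abs=1e-10)

    def test_sparsity_increases_with_lambda(self):
        rng = np.random.default_rng(21)
        f = random_features(rng, n=100, m=3)
        nnz_small = np.count_nonzero(fit_kl1lr(f, 0.01).coefficients)
        nnz_large = np.count_nonzero(fit_kl1lr(f, 0.3).coefficients)
        assert nnz_large <= nnz_small

    def test_negative_lambda_rejected(self):
        f = random_features(np.random.default_rng(0))
        with pytest.raises(ValueError):
            fit_kl1lr(f, lam=-0.1)


class TestPredictKL1LR:
    def test_zero_model_predicts_half(self):
        f = KL1LRFeatures(np.random.rand(4, 1), np.random.rand(4, 1))
        model = KL1LRModel(0.0, np.zeros(2), 0.0)
        np.testing.assert_array_equal(predict_kl1lr(model, f), 0.5)

    def test_large_intercept_saturates(self):
        f = KL1LRFeatures(np.zeros((3, 1)), np.zeros((3, 1)))
        model = KL1LRModel(30.0, np.zeros(2), 0.0)
        assert np.all(predict_kl1lr(model, f) > 0.999999)

    def test_worked_arithmetic(self):
        f = KL1LRFeatures(np.array([[0.8]]), np.array([[0.2]]))
        model = KL1LRModel(0.0, np.array([1.0, -1.0]), 0.0)
        assert predict_kl1lr(model, f)[0] == pytest.approx(1 / (1 + np.exp(-0.6)))

    def test_dimension_mismatch_rejected(self):
        f = KL1LRFeatures(np.zeros((2, 2)), np.zeros((2, 2)))
        model = KL1LRModel(0.0, np.zeros(2), 0.0)
        with pytest.raises(ValueError, match="coefficient count"):
            predict_kl1lr(model, f)


class TestSVM:
    def _two_cluster_kernel(self, n=40, gap=4.0, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        x = y * gap + rng.normal(scale=0.2, size=n)
        k = np.outer(x, x)  # linear kernel of a separable 1-D embedding
        return kernel_from(k + 1e-8 * np.eye(n)), y

    def test_separable_clusters_rank_perfectly(self):
        k, y = self._two_cluster_kernel()
        held = np.array([0, 1, 18, 19, 20, 21, 38, 39])
        train = np.setdiff1d(np.arange(40), held)
        probs = fit_svm(SVMSpec(cost=1.0, kernel=k), y, train, held)
        assert roc_auc(probs, y[held]) == 1.0
        assert np.all((probs > 0) & (probs < 1))

    def test_label_permutation_null_auc(self):
        rng = np.random.default_rng(2)
        n = 100
        k = random_psd_matrix(rng, n)
        held = np.arange(0, n, 4)
        train = np.setdiff1d(np.arange(n), held)
        aucs = []
        for _ in range(25):
            y = rng.permutation(np.repeat([0, 1], n // 2))
            probs = fit_svm(SVMSpec(cost=1.0, kernel=k), y, train, held)
            aucs.append(roc_auc(probs, y[held]))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_cost_sweep_range_accepted(self):
        k, y = self._two_cluster_kernel()
        train = np.arange(0, 40, 2)
        held = np.arange(1, 40, 2)
        for c in (0.1, 1.0, 100.0):
            probs = fit_svm(SVMSpec(cost=c, kernel=k), y, train, held)
            assert probs.shape == held.shape

    def test_deterministic(self):
        k, y = self._two_cluster_kernel(seed=4)
        train = np.arange(0, 40, 2)
        held = np.arange(1, 40, 2)
        p1 = fit_svm(SVMSpec(cost=2.0, kernel=k), y, train, held)
        p2 = fit_svm(SVMSpec(cost=2.0, kernel=k), y, train, held)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_training_rejected(self):
        k, y = self._two_cluster_kernel()
        with pytest.raises(ValueError, match="single class"):
            fit_svm(SVMSpec(cost=1.0, kernel=k), y, np.arange(10), np.arange(30, 40))

    def test_invalid_cost_rejected(self):
        k, _ = self._two_cluster_kernel()
        with pytest.raises(ValueError):
            SVMSpec(cost=0.0, kernel=k)
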