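import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.covariance import ledoit_wolf_shrinkage

from nirsbag import (
    fit_bagging,
    fit_lda,
    fit_linear_svm,
    fit_one_vs_one,
    ledoit_wolf_gamma,
    predict_majority,
)
from nirsbag.errors import DomainError, ModelError, SampleSizeError
from tests.conftest import weak_gaussian_features


def naive_lda_scores(X, y, xq, gamma=0.0):
    """Independent straight-from-the-formula LDA oracle (explicit
    inverse, per-class loops)."""
    cls = sorted(set(y))
    n, d = X.shape
    scatter = np.zeros((d, d))
    mus, pis = [], []
    for c in cls:
        Xc = X[np.asarray(y) == c]
        mu = Xc.mean(axis=0)
        mus.append(mu)
        pis.append(len(Xc) / n)
        scatter += (Xc - mu).T @ (Xc - mu)
    sigma = scatter / (n - len(cls))
    sigma_g = (1 - gamma) * sigma + gamma * np.eye(d)
    si = np.linalg.inv(sigma_g)
    cols = [np.log(pi) - 0.5 * mu @ si @ mu + np.atleast_2d(xq) @ si @ mu
            for mu, pi in zip(mus, pis)]
    return np.column_stack(cols)


class TestLDA:
    def test_1d_hand_example(self):
        X = np.array([[0.0], [2.0], [4.0], [6.0]])
        y = ["A", "A", "B", "B"]
        m = fit_lda(X, y, gamma=0.0)
        np.testing.assert_allclose(m.means.ravel(), [1.0, 5.0])
        np.testing.assert_allclose(m.pooled_cov, [[2.0]])
        np.testing.assert_allclose(m.priors, [0.5, 0.5])
        # equal-prior boundary at the midpoint x = 3
        assert m.predict(np.array([2.9])) == "A"
        assert m.predict(np.array([3.1])) == "B"
        sa, sb = m.scores(np.array([3.0]))
        assert sa == pytest.approx(sb, abs=1e-12)

    def test_gamma_one_gives_identity_covariance(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5)) * 7.0
        y = ["a"] * 15 + ["b"] * 15
        m = fit_lda(X, y, gamma=1.0)
        np.testing.assert_allclose(m.regularized_covariance, np.eye(5),
                                   atol=1e-12)
        # closed form: log pi - ||mu||^2/2 + x.mu
        xq = rng.standard_normal(5)
        expected = [
            np.log(p) - 0.5 * mu @ mu + xq @ mu
            for p, mu in zip(m.priors, m.means)
        ]
        np.testing.assert_allclose(m.scores(xq), expected, atol=1e-10)

    def test_duplicated_dataset_same_decisions(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 3))
        y = ["a"] * 10 + ["b"] * 10
        m1 = fit_lda(X, y, gamma=0.0)
        m2 = fit_lda(np.vstack([X, X]), y + y, gamma=0.0)
        np.testing.assert_allclose(m2.means, m1.means, atol=1e-12)
        Xt = rng.standard_normal((40, 3))
        s1, s2 = m1.scores(Xt), m2.scores(Xt)
        # covariance divisor changes ((N-K) vs (2N-K)) but the score
        # differences keep the same sign, so decisions are identical
        np.testing.assert_array_equal(np.argmax(s1, axis=1),
                                      np.argmax(s2, axis=1))

    def test_class_means_classified_to_own_class(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            means = rng.standard_normal((3, 4)) * 3.0
            X = np.vstack([m + 0.1 * rng.standard_normal((10, 4))
                           for m in means])
            y = np.repeat(list("abc"), 10)
            model = fit_lda(X, y, gamma=0.1)
            for k in range(3):
                assert model.predict(model.means[k]) == model.classes[k]

    def test_matches_independent_plain_lda(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((120, 6))
        y = np.repeat(list("abc"), 40)
        X[y == "b"] += 1.0
        m = fit_lda(X, y, gamma=0.0)
        Xt = rng.standard_normal((30, 6))
        np.testing.assert_allclose(
            m.scores(Xt), naive_lda_scores(X, y, Xt), atol=1e-8
        )
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        np.testing.assert_array_equal(m.predict(Xt), sk.predict(Xt))

    def test_small_class_rejected(self):
        with pytest.raises(SampleSizeError):
            fit_lda(np.zeros((3, 2)), ["a", "a", "b"], gamma=0.5)

    @given(gamma=st.floats(1e-6, 1.0), seed=st.integers(0, 100))
    def test_regularized_covariance_positive_definite(self, gamma, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((4, 6))
        psd = A @ A.T  # rank-deficient PSD possible
        X = rng.multivariate_normal(np.zeros(4), psd + 1e-9 * np.eye(4),
                                    size=12)
        m = fit_lda(X, ["a"] * 6 + ["b"] * 6, gamma=gamma)
        w = np.linalg.eigvalsh(m.regularized_covariance)
        assert w.min() >= gamma - 1e-12


class TestLedoitWolf:
    def test_identical_rows_full_shrinkage(self):
        X = np.tile([1.0, 2.0, 3.0], (10, 1))
        assert ledoit_wolf_gamma(X) == 1.0

    def test_clipped_to_unit_interval(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((rng.integers(2, 50), 8))
            assert 0.0 <= ledoit_wolf_gamma(X) <= 1.0

    def test_shrinkage_decreases_with_sample_size(self):
        rng = np.random.default_rng(42)
        cov = np.diag(np.linspace(0.5, 3.0, 8))
        gammas = {}
        for n in (100, 10_000):
            vals = [
                ledoit_wolf_gamma(
                    np.random.default_rng(s).multivariate_normal(
                        np.zeros(8), cov, size=n
                    )
                )
                for s in range(10)
            ]
            gammas[n] = np.mean(vals)
        assert gammas[10_000] < gammas[100]

    def test_matches_sklearn_on_centered_data(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((60, 12)) @ rng.standard_normal((12, 12))
        Xc = X - X.mean(axis=0)
        assert ledoit_wolf_gamma(Xc, centered=True) == pytest.approx(
            ledoit_wolf_shrinkage(Xc, assume_centered=True), abs=1e-12
        )

    def test_single_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            ledoit_wolf_gamma(np.zeros((1, 3)))


class TestBagging:
    def test_seeded_determinism(self):
        fm = weak_gaussian_features(0)
        e1 = fit_bagging(fm, n_learn=7, seed=123)
        e2 = fit_bagging(fm, n_learn=7, seed=123)
        np.testing.assert_array_equal(e1.resample_indices,
                                      e2.resample_indices)
        for a, b in zip(e1.weak_learners, e2.weak_learners):
            np.testing.assert_array_equal(a.means, b.means)

    def test_resamples_have_training_set_size(self):
        fm = weak_gaussian_features(1)
        ens = fit_bagging(fm, n_learn=5, seed=0)
        assert ens.resample_indices.shape == (5, fm.n_trials)

    def test_single_learner_ensemble_equals_weak_learner(self):
        fm = weak_gaussian_features(2)
        ens = fit_bagging(fm, n_learn=1, seed=9)
        np.testing.assert_array_equal(
            predict_majority(ens, fm.values),
            ens.weak_learners[0].predict(fm.values),
        )

    def test_no_resampling_hook_matches_single_rlda(self):
        fm = weak_gaussian_features(3)
        ens = fit_bagging(fm, n_learn=15, seed=0, resample=False)
        single = fit_lda(fm, gamma=0.1)
        np.testing.assert_array_equal(
            predict_majority(ens, fm.values), single.predict(fm.values)
        )

    def test_json_roundtrip(self):
        from nirsbag.classifiers import BaggingEnsembleModel

        fm = weak_gaussian_features(4)
        ens = fit_bagging(fm, n_learn=3, seed=1)
        back = BaggingEnsembleModel.from_dict(ens.to_dict())
        np.testing.assert_array_equal(
            predict_majority(back, fm.values),
            predict_majority(ens, fm.values),
        )


class _FixedVoteModel:
    """Weak-learner stand-in that always votes one class."""

    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.asarray([self.label] * np.atleast_2d(X).shape[0],
                          dtype=object)


def _vote_ensemble(votes):
    from nirsbag.classifiers import BaggingEnsembleModel

    classes = sorted(set(votes))
    if len(classes) == 1:  # ensure >= 2 classes in the model
        classes = sorted(set(votes) | {"zz"})
    return BaggingEnsembleModel(
        classes=classes,
        weak_learners=[_FixedVoteModel(v) for v in votes],
        resample_indices=np.zeros((len(votes), 1), dtype=int),
        gamma=0.1,
        seed=0,
    )


class TestMajorityVote:
    def test_simple_binary_vote(self):
        ens = _vote_ensemble(["+1", "+1", "-1"])
        assert predict_majority(ens, np.zeros(1)) == "+1"

    def test_exhaustive_sign_rule_oracle(self):
        """Plurality over ±1 votes equals sign(sum of signs) for every
        odd-size vote vector up to 5."""
        for n in (1, 3, 5):
            for combo in itertools.product([-1, 1], repeat=n):
                expected = "+1" if np.sign(sum(combo)) > 0 else "-1"
                ens = _vote_ensemble(
                    ["+1" if v > 0 else "-1" for v in combo]
                )
                assert predict_majority(ens, np.zeros(1)) == expected

    def test_ternary_tie_flagged_lowest_class(self):
        ens = _vote_ensemble(["A", "A", "B", "C", "C"])
        label, tie, votes = predict_majority(ens, np.zeros(1),
                                             return_record=True)
        assert label == "A" and tie is True
        assert votes.shape == (5, 1)

    def test_vote_permutation_invariance(self):
        fm = weak_gaussian_features(5)
        ens = fit_bagging(fm, n_learn=9, seed=2)
        base = predict_majority(ens, fm.values)
        rng = np.random.default_rng(0)
        perm = rng.permutation(9)
        ens.weak_learners = [ens.weak_learners[i] for i in perm]
        np.testing.assert_array_equal(predict_majority(ens, fm.values),
                                      base)

    def test_empty_ensemble_rejected(self):
        ens = _vote_ensemble(["A"])
        ens.weak_learners = []
        with pytest.raises(ModelError):
            predict_majority(ens, np.zeros(1))


class TestOneVsOne:
    def test_pair_count(self, separable_blobs):
        m = fit_one_vs_one(separable_blobs)
        assert len(m.models) == 3 and len(m.pairs) == 3

    def test_separable_blobs_training_accuracy(self, separable_blobs):
        m = fit_one_vs_one(separable_blobs)
        pred = m.predict(separable_blobs.values)
        assert np.mean(pred == np.asarray(separable_blobs.labels,
                                          dtype=object)) == 1.0

    def test_two_classes_reduces_to_base(self):
        fm = weak_gaussian_features(6)
        ovo = fit_one_vs_one(fm)
        base = fit_lda(fm, gamma=0.0)
        np.testing.assert_array_equal(ovo.predict(fm.values),
                                      base.predict(fm.values))


def dual_qp_linear_svm(X, y01, C=1.0):
    """Independent soft-margin linear SVM via the dual QP
    (scipy SLSQP), for small problems only."""
    from scipy.optimize import minimize

    ys = np.where(np.asarray(y01) == 1, 1.0, -1.0)
    n = X.shape[0]
    K = (X @ X.T) * np.outer(ys, ys)

    def neg_dual(a):
        return 0.5 * a @ K @ a - a.sum()

    res = minimize(
        neg_dual,
        np.full(n, C / 2),
        jac=lambda a: K @ a - 1.0,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ ys,
                      "jac": lambda a: ys}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    a = res.x
    w = (a * ys) @ X
    margin = (a > 1e-6) & (a < C - 1e-6)
    if margin.any():
        b = np.mean(ys[margin] - X[margin] @ w)
    else:  # fall back to midpoint rule
        b = -(np.max(X[ys == -1] @ w) + np.min(X[ys == 1] @ w)) / 2
    return w, b


class TestLinearSVM:
    def test_separable_points(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [5.0, 5.0], [5.0, 6.0]])
        y = ["a", "a", "b", "b"]
        m = fit_linear_svm(X, y)
        np.testing.assert_array_equal(m.predict(X), np.asarray(y,
                                                               dtype=object))
        assert m.predict(np.array([2.5, 3.0])) in {"a", "b"}

    def test_standardization_contract(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3)) * [1.0, 10.0, 0.01] + [5, -2, 0]
        m = fit_linear_svm(X, ["a"] * 20 + ["b"] * 20)
        Z = (X - m.mean) / m.scale
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_zero_variance_feature_handled(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        m = fit_linear_svm(X, ["a"] * 5 + ["b"] * 5)
        assert m.scale[1] == 1.0

    def test_agreement_with_dual_qp_oracle(self):
        agree = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((20, 2)) + np.repeat(
                [[0, 0], [1.5, 1.5]], 10, axis=0
            )
            y = np.array([0] * 10 + [1] * 10)
            labels = np.where(y == 1, "b", "a")
            m = fit_linear_svm(X, labels)
            Z = (X - m.mean) / m.scale
            w, b = dual_qp_linear_svm(Z, y)
            Xt = rng.standard_normal((20, 2)) * 2
            Zt = (Xt - m.mean) / m.scale
            dec = Zt @ w + b
            keep = np.abs(dec) > 1e-3  # exclude boundary ties
            oracle = np.where(dec[keep] > 0, "b", "a")
            if np.array_equal(np.asarray(m.predict(Xt[keep])), oracle):
                agree += 1
        assert agree >= 49

    def test_bad_cost_rejected(self):
        with pytest.raises(DomainError):
            fit_linear_svm(np.zeros((4, 2)), ["a", "a", "b", "b"], cost=0.0)
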