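"""LDA decoder: oracle equivalence, tie rules, shrinkage behavior."""

import numpy as np
import pytest
from scipy import stats as spstats

from myotrain.classify import (
    LDAModel,
    SingularCovarianceError,
    classification_accuracy,
    fit_lda,
    predict,
    predict_batch,
)
from myotrain.core import LabelStream
from myotrain.signal import FeatureMatrix


def make_features(X, y, n_channels=None):
    """Wrap a raw (X, y) pair as a FeatureMatrix for the decoder API."""
    X = np.asarray(X, dtype=float)
    if n_channels is None:
        assert X.shape[1] % 4 == 0
        n_channels = X.shape[1] // 4
    return FeatureMatrix(
        X, np.arange(len(X), dtype=float), LabelStream(np.asarray(y)), n_channels
    )


def gaussian_toy(rng, n_classes=3, dim=5, n_per_class=40, spread=4.0):
    """Random shared-covariance Gaussian problem (dim padded to C*4)."""
    A = rng.standard_normal((dim, dim))
    cov = A @ A.T + dim * np.eye(dim)
    means = spread * rng.standard_normal((n_classes, dim))
    X = np.vstack([
        rng.multivariate_normal(mu, cov, size=n_per_class) for mu in means
    ])
    y = np.repeat(np.arange(n_classes), n_per_class)
    return X, y


def bayes_log_posterior(X, means, cov, priors):
    """Explicit equal-covariance Gaussian log-posterior (up to the shared
    constant): log pi_k - (x - mu_k)' cov^-1 (x - mu_k) / 2."""
    inv = np.linalg.inv(cov)
    out = np.empty((len(X), len(means)))
    for k, mu in enumerate(means):
        d = X - mu
        out[:, k] = np.log(priors[k]) - 0.5 * np.einsum("nd,dc,nc->n", d, inv, d)
    return out


class TestFitLDA:
    def test_two_symmetric_1d_classes_have_boundary_at_zero(self):
        # 1-D feature space embedded as a single synthetic column set
        X = np.array([[-1.0], [-1.1], [-0.9], [1.0], [1.1], [0.9]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_lda((X, y), shrinkage=0.0)
        g = model.discriminants(np.array([[0.0]]))[0]
        assert abs(g[0] - g[1]) < 1e-9  # boundary exactly at the midpoint

    def test_duplicate_feature_columns_raise_singular_error(self, rng):
        X = rng.standard_normal((40, 3))
        X = np.hstack([X, X[:, :1]])  # exact duplicate column
        y = np.repeat([0, 1], 20)
        with pytest.raises(SingularCovarianceError, match="shrinkage"):
            fit_lda((X, y), shrinkage=0.0)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError, match="2 classes"):
            fit_lda((X, np.zeros(10, dtype=int)))

    def test_unlabeled_windows_excluded_from_fit(self, rng):
        X, y = gaussian_toy(rng)
        y2 = y.copy()
        # poison some windows with huge values but mark them unlabeled
        X2 = np.vstack([X, 1e6 * np.ones((5, X.shape[1]))])
        y2 = np.concatenate([y, np.full(5, -1)])
        m_ref = fit_lda((X, y), shrinkage=0.0)
        m_aug = fit_lda((X2, y2), shrinkage=0.0)
        assert np.allclose(m_ref.means, m_aug.means)
        assert np.allclose(m_ref.pooled_covariance, m_aug.pooled_covariance)

    def test_priors_are_class_frequencies_unless_uniform(self, rng):
        X = np.vstack([rng.standard_normal((30, 2)), 5 + rng.standard_normal((10, 2))])
        y = np.repeat([0, 1], [30, 10])
        model = fit_lda((X, y))
        assert model.priors == pytest.approx([0.75, 0.25])
        uni = fit_lda((X, y), uniform_priors=True)
        assert uni.priors == pytest.approx([0.5, 0.5])

    def test_pooled_covariance_matches_direct_formula(self, rng):
        X, y = gaussian_toy(rng, n_classes=2, dim=4, n_per_class=25)
        model = fit_lda((X, y), shrinkage=0.0)
        scatter = np.zeros((4, 4))
        for k in (0, 1):
            Z = X[y == k] - X[y == k].mean(axis=0)
            scatter += Z.T @ Z
        assert np.allclose(model.pooled_covariance, scatter / (50 - 2))

    def test_shrinkage_interpolates_toward_scaled_identity(self, rng):
        X, y = gaussian_toy(rng, n_classes=2, dim=4, n_per_class=25)
        s0 = fit_lda((X, y), shrinkage=0.0).pooled_covariance
        s1 = fit_lda((X, y), shrinkage=1.0).pooled_covariance
        assert np.allclose(s1, (np.trace(s0) / 4) * np.eye(4))


class TestPredict:
    def test_class_mean_maps_to_its_class(self, basic_model):
        for k, mu in zip(basic_model.class_ids, basic_model.means):
            pred, _ = predict(basic_model, mu)
            assert pred == k

    def test_exact_midpoint_tie_breaks_to_lower_id(self):
        X = np.array([[-1.0], [1.0], [1.0], [3.0]])
        y = np.array([3, 3, 7, 7])
        model = fit_lda((X, y), shrinkage=0.0)
        pred, scores = predict(model, np.array([1.0]))  # exact midpoint
        assert scores[0] == pytest.approx(scores[1], abs=1e-12)
        assert pred == 3

    def test_dimension_mismatch_rejected(self, basic_model):
        with pytest.raises(ValueError, match="dimensions"):
            predict(basic_model, np.zeros(5))

    def test_agreement_with_bayes_log_posterior_oracle(self, rng):
        for _ in range(5):
            X, y = gaussian_toy(rng)
            model = fit_lda((X, y), shrinkage=0.0)
            scores = model.discriminants(X)
            oracle = bayes_log_posterior(
                X, model.means, model.pooled_covariance, model.priors
            )
            # identical up to the class-independent -x'S^-1x/2 term
            shift = scores - oracle
            assert np.allclose(shift, shift[:, :1], atol=1e-8)
            assert np.array_equal(
                np.argmax(scores, axis=1), np.argmax(oracle, axis=1)
            )

    def test_agreement_with_mahalanobis_oracle_under_equal_priors(self, rng):
        X, y = gaussian_toy(rng, n_classes=4)
        model = fit_lda((X, y), shrinkage=0.0, uniform_priors=True)
        probes = rng.standard_normal((100, X.shape[1])) * 3
        preds = predict_batch(model, probes)
        inv = np.linalg.inv(model.pooled_covariance)
        d2 = np.array([
            np.einsum("nd,dc,nc->n", probes - mu, inv, probes - mu)
            for mu in model.means
        ]).T
        assert np.array_equal(preds, model.class_ids[np.argmin(d2, axis=1)])

    def test_agreement_with_sklearn_reference(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = gaussian_toy(rng, n_classes=3, dim=5, n_per_class=60)
        model = fit_lda((X, y), shrinkage=0.0)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        probes = rng.standard_normal((200, 5)) * 3
        assert np.mean(predict_batch(model, probes) == ref.predict(probes)) > 0.98

    def test_predictions_invariant_under_invertible_linear_map(self, rng):
        X, y = gaussian_toy(rng, n_classes=3, dim=5)
        probes = rng.standard_normal((50, 5)) * 2
        base = predict_batch(fit_lda((X, y), shrinkage=0.0), probes)
        for _ in range(3):
            A = rng.standard_normal((5, 5)) + 2 * np.eye(5)
            mapped = predict_batch(fit_lda((X @ A.T, y), shrinkage=0.0), probes @ A.T)
            assert np.array_equal(base, mapped)


class TestClassificationAccuracy:
    def test_perfect_when_classes_far_apart(self, rng):
        X = np.vstack([rng.standard_normal((50, 4)), 50 + rng.standard_normal((50, 4))])
        y = np.repeat([0, 1], 50)
        feats = make_features(X, y)
        model = fit_lda(feats)
        assert classification_accuracy(model, feats) == 100.0

    def test_identical_distributions_score_near_fifty(self, rng):
        X = rng.standard_normal((2000, 4))
        y = np.tile([0, 1], 1000)
        feats = make_features(X, y)
        model = fit_lda(feats)
        assert classification_accuracy(model, feats) == pytest.approx(50.0, abs=5.0)

    def test_uniform_random_predictor_over_eleven_classes_hits_chance(self, rng):
        draws = rng.integers(0, 11, size=10_000)
        truth = rng.integers(0, 11, size=10_000)
        acc = 100.0 * np.mean(draws == truth)
        assert acc == pytest.approx(100.0 / 11.0, abs=1.0)

    def test_no_labeled_windows_rejected(self, rng, basic_model):
        feats = make_features(rng.standard_normal((5, 32)), np.full(5, -1))
        with pytest.raises(ValueError, match="labeled"):
            classification_accuracy(basic_model, feats)
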