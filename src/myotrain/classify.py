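"""Linear discriminant analysis for motion decoding.

The decoder assumes Gaussian class-conditional feature distributions with a
shared covariance, which yields linear decision boundaries.  The pooled
within-class covariance is shrunk toward a scaled identity,

    Sigma(lambda) = (1 - lambda) * S + lambda * (tr(S) / D) * I,

because the 32-dimensional feature space is frequently rank-deficient when
trained on short (2 s per motion) bursts; the default ``lambda = 1e-3`` is
the minimal fix and leaves well-conditioned fits essentially untouched.

Decoding evaluates the linear discriminant

    g_k(x) = x' Sigma^-1 mu_k - 1/2 mu_k' Sigma^-1 mu_k + ln pi_k

and returns the argmax, breaking exact ties by the lowest class id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import UNLABELED
from .signal import FeatureMatrix

__all__ = ["LDAModel", "fit_lda", "predict", "predict_batch", "classification_accuracy"]


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled covariance is singular; refit with a positive shrinkage."""


@dataclass
class LDAModel:
    """Trained LDA decoder: class means, shrunk pooled covariance, priors."""

    class_ids: np.ndarray          # K, sorted ascending
    means: np.ndarray              # K x D
    pooled_covariance: np.ndarray  # D x D, after shrinkage
    priors: np.ndarray             # K, sums to 1
    shrinkage_lambda: float
    # Precomputed discriminant weights: w_k = Sigma^-1 mu_k, b_k = -mu_k'w_k/2 + ln pi_k
    _weights: np.ndarray = None  # type: ignore[assignment]
    _biases: np.ndarray = None   # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.class_ids = np.asarray(self.class_ids, dtype=np.int64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.pooled_covariance = np.asarray(self.pooled_covariance, dtype=np.float64)
        self.priors = np.asarray(self.priors, dtype=np.float64)
        if abs(self.priors.sum() - 1.0) > 1e-12:
            raise ValueError("class priors must sum to 1")
        if not np.allclose(self.pooled_covariance, self.pooled_covariance.T):
            raise ValueError("pooled covariance must be symmetric")
        if not 0.0 <= self.shrinkage_lambda <= 1.0:
            raise ValueError("shrinkage lambda must lie in [0, 1]")
        if self._weights is None:
            self._solve()

    def _solve(self) -> None:
        try:
            chol = np.linalg.cholesky(self.pooled_covariance)
        except np.linalg.LinAlgError as exc:
            raise SingularCovarianceError(
                "pooled covariance is singular or indefinite; refit with a "
                "positive shrinkage lambda (e.g. fit_lda(..., shrinkage=1e-3))"
            ) from exc
        # w_k = Sigma^-1 mu_k via two triangular solves
        from scipy.linalg import solve_triangular

        tmp = solve_triangular(chol, self.means.T, lower=True)
        self._weights = solve_triangular(chol.T, tmp, lower=False).T  # K x D
        self._biases = (
            -0.5 * np.einsum("kd,kd->k", self.means, self._weights)
            + np.log(self.priors)
        )

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def discriminants(self, X: np.ndarray) -> np.ndarray:
        """Per-class discriminant scores g_k(x) for rows of X (N x K)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature vector has {X.shape[1]} dimensions, model expects "
                f"{self.n_features}"
            )
        return X @ self._weights.T + self._biases


def fit_lda(
    features: FeatureMatrix | tuple[np.ndarray, np.ndarray],
    shrinkage: float = 1e-3,
    uniform_priors: bool = False,
) -> LDAModel:
    """Fit the LDA decoder to labeled feature windows.

    Unlabeled windows (label −1) are excluded.  Class means are sample
    means; the pooled covariance is the within-class scatter divided by
    ``N - K``, then shrunk toward ``(tr(S)/D) * I`` by ``shrinkage``.
    Priors default to class frequencies; ``uniform_priors`` overrides (the
    training protocol presents balanced repetitions by design).
    """
    if isinstance(features, FeatureMatrix):
        X, y = features.values, features.labels.labels
    else:
        X, y = features
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
    keep = y != UNLABELED
    X, y = X[keep], y[keep]
    class_ids = np.unique(y)
    if class_ids.size < 2:
        raise ValueError(
            f"LDA requires at least 2 classes, got {class_ids.size}"
        )
    counts = np.array([np.sum(y == k) for k in class_ids])
    if np.any(counts < 2):
        short = class_ids[counts < 2].tolist()
        raise ValueError(f"every class needs >= 2 windows; classes {short} have fewer")

    K, (N, D) = class_ids.size, X.shape
    means = np.vstack([X[y == k].mean(axis=0) for k in class_ids])
    scatter = np.zeros((D, D))
    for k, mu in zip(class_ids, means):
        Z = X[y == k] - mu
        scatter += Z.T @ Z
    S = scatter / (N - K)
    lam = float(shrinkage)
    cov = (1.0 - lam) * S + lam * (np.trace(S) / D) * np.eye(D)
    # Guard against numerically indefinite (not just ill-conditioned) input.
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[-1] <= 0 or eigvals[0] <= eigvals[-1] * 1e-12:
        raise SingularCovarianceError(
            "pooled covariance is singular (e.g. duplicated feature columns); "
            "refit with a positive shrinkage lambda"
        )
    priors = (
        np.full(K, 1.0 / K) if uniform_priors else counts / counts.sum()
    )
    return LDAModel(class_ids, means, cov, priors, lam)


def _argmax_lowest_id(scores: np.ndarray) -> np.ndarray:
    """First index whose score is within rounding error of the row maximum.

    Discriminant ties (e.g. a probe exactly between two equal-prior class
    means) land a few ulp apart after the linear algebra, so ties are
    resolved up to a tiny score tolerance — and to the lowest class id,
    since class_ids are sorted ascending.
    """
    smax = scores.max(axis=1, keepdims=True)
    tol = 1e-9 * np.maximum(1.0, np.abs(smax))
    return np.argmax(scores >= smax - tol, axis=1)


def predict(model: LDAModel, x: np.ndarray) -> tuple[int, np.ndarray]:
    """Decode one feature vector: ``(class id, per-class scores)``.

    Ties break to the lowest class id.
    """
    scores = model.discriminants(x)
    return int(model.class_ids[_argmax_lowest_id(scores)[0]]), scores[0]


def predict_batch(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Decode many feature vectors at once (returns class ids)."""
    scores = model.discriminants(X)
    return model.class_ids[_argmax_lowest_id(scores)]


def classification_accuracy(model: LDAModel, features: FeatureMatrix) -> float:
    """Percent of labeled windows decoded correctly."""
    labeled = features.labeled()
    if len(labeled) == 0:
        raise ValueError("no labeled windows to score")
    pred = predict_batch(model, labeled.values)
    return 100.0 * float(np.mean(pred == labeled.labels.labels))
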