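"""Regularized Fisher Discriminant Analysis with a Mahalanobis class rule.

For a two-class training set {(z_i, y_i)}, y_i in {+1, -1}, the projection

    w = (S_W + lambda I)^{-1} (m_1 - m_{-1})

maximizes the Fisher criterion <w, m_1 - m_{-1}>^2 / (w^T S_W w + lambda
||w||^2), where S_W is the (unnormalized) within-class scatter matrix --
the sum over both classes of outer products of deviations from the class
mean -- and m_j are the class feature means. lambda = 0 recovers canonical
FDA; lambda > 0 shrinks the scatter estimate toward the identity, which is
essential when the feature count approaches the sample count.

A sample z is scored by s(z) = <w, z>, and classified to the class whose
training-score distribution is nearest in Mahalanobis distance:

    yhat = argmin_j (s(z) - mu_j)^2 / sigma_j^2

with mu_j, sigma_j^2 the mean and variance of training scores in class j.
Exact ties break to -1 (nontarget), the conservative choice for an oddball
paradigm where targets are the rare class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "ScatterStats",
    "FDAModel",
    "compute_scatter",
    "solve_projection",
    "fit",
    "score",
    "score_many",
    "predict",
    "predict_scores",
]


@dataclass
class ScatterStats:
    """Within-class scatter and class means of a two-class sample."""

    S_W: np.ndarray
    m_pos: np.ndarray
    m_neg: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class FDAModel:
    """Fitted projection plus the training-score statistics of each class."""

    w: np.ndarray
    lam: float
    mu_pos: float
    mu_neg: float
    var_pos: float
    var_neg: float
    m_pos: np.ndarray
    m_neg: np.ndarray

    @property
    def n_features(self) -> int:
        return self.w.shape[0]

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "lambda": self.lam,
            "mu_pos": self.mu_pos,
            "mu_neg": self.mu_neg,
            "var_pos": self.var_pos,
            "var_neg": self.var_neg,
        }


def compute_scatter(Z: np.ndarray, y: np.ndarray) -> ScatterStats:
    """Within-class scatter S_W = sum_j sum_{i in K_j} (z_i - m_j)(z_i - m_j)^T.

    No 1/n normalization is applied. Both classes must be present.
    """
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y)
    if Z.ndim != 2 or Z.shape[0] != y.shape[0]:
        raise ValueError("Z must be (samples, features) matching y")
    pos = Z[y == 1]
    neg = Z[y == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes (+1, -1) must be present")
    m_pos = pos.mean(axis=0)
    m_neg = neg.mean(axis=0)
    dev_pos = pos - m_pos
    dev_neg = neg - m_neg
    S_W = dev_pos.T @ dev_pos + dev_neg.T @ dev_neg
    return ScatterStats(S_W=S_W, m_pos=m_pos, m_neg=m_neg,
                        n_pos=len(pos), n_neg=len(neg))


def solve_projection(S_W: np.ndarray, mean_diff: np.ndarray, lam: float) -> np.ndarray:
    """Solve (S_W + lambda I) w = m_1 - m_{-1} as a linear system.

    Never inverts explicitly. For lambda > 0 the matrix is symmetric
    positive definite and a Cholesky solve is used; severe ill-conditioning
    falls back to a symmetric solve, then least squares. lambda = 0 with a
    singular S_W raises an informative error.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    A = S_W + lam * np.eye(S_W.shape[0])
    if lam == 0:
        # Cholesky doubles as the singularity check: S_W is PSD, so it
        # factors iff S_W is (numerically) full rank
        try:
            c, low = linalg.cho_factor(A)
            return linalg.cho_solve((c, low), mean_diff)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                "S_W is rank-deficient with lambda = 0; use lambda > 0"
            ) from exc
    try:
        c, low = linalg.cho_factor(A, check_finite=False)
        return linalg.cho_solve((c, low), mean_diff, check_finite=False)
    except linalg.LinAlgError:
        try:
            return linalg.solve(A, mean_diff, assume_a="sym")
        except linalg.LinAlgError:
            return linalg.lstsq(A, mean_diff)[0]


def fit(Z: np.ndarray, y: np.ndarray, lam: float) -> FDAModel:
    """Fit the regularized projection and the per-class score statistics.

    Requires at least 2 samples in each class (score variances use the
    unbiased n-1 denominator and must be positive).
    """
    stats = compute_scatter(Z, y)
    if stats.n_pos < 2 or stats.n_neg < 2:
        raise ValueError("each class needs >= 2 samples to estimate score variance")
    w = solve_projection(stats.S_W, stats.m_pos - stats.m_neg, lam)
    scores = np.asarray(Z, dtype=np.float64) @ w
    s_pos = scores[np.asarray(y) == 1]
    s_neg = scores[np.asarray(y) == -1]
    var_pos = float(s_pos.var(ddof=1))
    var_neg = float(s_neg.var(ddof=1))
    if var_pos <= 0 or var_neg <= 0:
        raise ValueError("degenerate training scores: zero within-class variance")
    return FDAModel(
        w=w,
        lam=float(lam),
        mu_pos=float(s_pos.mean()),
        mu_neg=float(s_neg.mean()),
        var_pos=var_pos,
        var_neg=var_neg,
        m_pos=stats.m_pos,
        m_neg=stats.m_neg,
    )


def score(model: FDAModel, z: np.ndarray) -> float:
    """Projection score s(z) = <w, z>."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape != model.w.shape:
        raise ValueError(f"feature vector has shape {z.shape}, expected {model.w.shape}")
    return float(model.w @ z)


def score_many(model: FDAModel, Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[1] != model.n_features:
        raise ValueError("feature dimension mismatch")
    return Z @ model.w


def predict_scores(model: FDAModel, s: np.ndarray) -> np.ndarray:
    """Mahalanobis class rule applied to scores (vectorized).

    Returns +1 where (s - mu_+1)^2/var_+1 is strictly smaller than the
    nontarget distance, else -1 (ties included).
    """
    s = np.asarray(s, dtype=np.float64)
    d_pos = (s - model.mu_pos) ** 2 / model.var_pos
    d_neg = (s - model.mu_neg) ** 2 / model.var_neg
    return np.where(d_pos < d_neg, 1, -1).astype(np.int64)


def predict(model: FDAModel, s: float) -> int:
    """Class of a single score under the Mahalanobis rule."""
    return int(predict_scores(model, np.atleast_1d(s))[0])
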