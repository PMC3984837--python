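"""Multiobjective fitness: CV classification accuracy vs. channel count.

A candidate solution (a channel subset and an FDA regularization lambda) is
scored by the weighted aggregation

    F = w1 * f1 + w2 * f2,
    f1 = sqrt( (TP / Ps) * (TN / Ns) ),
    f2 = (N_Ch - n + 1) / N_Ch,

where TP/TN are pooled true positive/negative counts from 10-fold
stratified cross-validation of the FDA classifier on the training data,
Ps/Ns the class totals, n the number of selected channels and N_Ch the
montage size (64 by default). f1 is the geometric mean of the per-class
accuracies -- unbalanced classifiers are penalized harder than by the
arithmetic mean -- and f2 rises as channels are removed, reaching 1 for a
single channel. With w1 + w2 = 1 a perfect one-channel classifier attains
the maximum fitness F = 1.

Two implementations of the CV estimate are provided:

* :func:`cv_confusion` -- the plain reference path, refitting FDA per fold
  on the sliced feature matrix.
* :class:`CVFitnessEvaluator` -- the fast path used inside the swarm loop.
  It precomputes, once per search, each fold's full-montage within-class
  scatter and class means; because features are channel-blocked, the
  scatter of any channel subset is a submatrix, so evaluating a particle
  reduces to a submatrix slice plus one SPD solve per fold. The fold
  assignment is frozen once per search (one fold seed), making the fitness
  a deterministic function of the particle -- required for caching and for
  reproducible swarm runs.

Both paths share the fold construction and the linear solver, and agree on
their confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import fda

__all__ = [
    "FitnessWeights",
    "FitnessResult",
    "WEIGHT_CASES",
    "channel_objective",
    "gm_accuracy",
    "aggregate_fitness",
    "make_folds",
    "cv_confusion",
    "CVFitnessEvaluator",
]


@dataclass(frozen=True)
class FitnessWeights:
    """Aggregation weights (w1 accuracy, w2 channel parsimony); w1 + w2 = 1."""

    w1: float
    w2: float

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("weights must be nonnegative")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


#: The eight weight presets of the simulation study, from accuracy-only
#: (case1) to strongly parsimony-driven (case8).
WEIGHT_CASES: dict[str, FitnessWeights] = {
    "case1": FitnessWeights(1.00, 0.00),
    "case2": FitnessWeights(0.95, 0.05),
    "case3": FitnessWeights(0.90, 0.10),
    "case4": FitnessWeights(0.85, 0.15),
    "case5": FitnessWeights(0.75, 0.25),
    "case6": FitnessWeights(0.65, 0.35),
    "case7": FitnessWeights(0.50, 0.50),
    "case8": FitnessWeights(0.35, 0.65),
}


@dataclass
class FitnessResult:
    """Pooled CV confusion counts and the derived objectives."""

    tp: int
    tn: int
    fp: int
    fn: int
    ps: int
    ns: int
    gm: float
    n_channels: int
    f2: float
    fitness: float

    def as_record(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "Ps": self.ps, "Ns": self.ns, "n_channels": self.n_channels,
            "f1": self.gm, "f2": self.f2, "fitness": self.fitness,
        }


def channel_objective(n: int, n_total: int = 64) -> float:
    """Parsimony objective f2 = (N_Ch - n + 1) / N_Ch; 1 for one channel."""
    if n < 1:
        raise ValueError("at least one channel must be selected")
    if n > n_total:
        raise ValueError(f"n = {n} exceeds the montage size {n_total}")
    return (n_total - n + 1) / n_total


def gm_accuracy(tp: int, tn: int, ps: int, ns: int) -> float:
    """Geometric mean of true-positive and true-negative rates."""
    if ps <= 0 or ns <= 0:
        raise ValueError("both class totals must be positive")
    return float(np.sqrt((tp / ps) * (tn / ns)))


def aggregate_fitness(
    gm: float, n: int, weights: FitnessWeights, n_total: int = 64
) -> float:
    """Weighted aggregation F = w1 * f1 + w2 * f2."""
    return weights.w1 * gm + weights.w2 * channel_objective(n, n_total)


def make_folds(
    labels: np.ndarray, n_folds: int = 10, fold_seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold assignment: every fold keeps the class ratio (+-1).

    Deterministic in ``fold_seed``; shared by the reference and fast CV
    paths so they see identical folds.
    """
    labels = np.asarray(labels)
    counts = [np.sum(labels == c) for c in (-1, 1)]
    if min(counts) < n_folds:
        raise ValueError(
            f"need >= {n_folds} samples per class for {n_folds}-fold "
            f"stratified CV (got {counts})"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    return [
        (np.asarray(tr), np.asarray(te))
        for tr, te in skf.split(np.zeros((len(labels), 1)), labels)
    ]


def _result_from_counts(
    tp: int, tn: int, ps: int, ns: int, n_channels: int,
    weights: FitnessWeights, n_total: int,
) -> FitnessResult:
    gm = gm_accuracy(tp, tn, ps, ns)
    f2 = channel_objective(n_channels, n_total)
    return FitnessResult(
        tp=tp, tn=tn, fp=ns - tn, fn=ps - tp, ps=ps, ns=ns,
        gm=gm, n_channels=n_channels, f2=f2,
        fitness=weights.w1 * gm + weights.w2 * f2,
    )


def cv_confusion(
    features: np.ndarray,
    labels: np.ndarray,
    channels,
    lam: float,
    weights: FitnessWeights = FitnessWeights(0.5, 0.5),
    n_folds: int = 10,
    fold_seed: int = 0,
    n_channels_total: int | None = None,
) -> FitnessResult:
    """Reference CV fitness: refit FDA on each fold's training portion.

    ``features`` is the full-montage tensor (trials, channels, samples per
    channel); ``channels`` the 0-based subset to classify with. Confusion
    counts are pooled over the held-out folds before computing rates.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    channels = tuple(int(c) for c in channels)
    if not channels:
        raise ValueError("channel set is empty")
    if n_channels_total is None:
        n_channels_total = features.shape[1]
    Z = features[:, channels, :].reshape(features.shape[0], -1)
    tp = tn = 0
    for tr, te in make_folds(labels, n_folds, fold_seed):
        model = fda.fit(Z[tr], labels[tr], lam)
        pred = fda.predict_scores(model, fda.score_many(model, Z[te]))
        tp += int(np.sum((pred == 1) & (labels[te] == 1)))
        tn += int(np.sum((pred == -1) & (labels[te] == -1)))
    ps = int(np.sum(labels == 1))
    ns = int(np.sum(labels == -1))
    return _result_from_counts(tp, tn, ps, ns, len(channels), weights,
                               n_channels_total)


class CVFitnessEvaluator:
    """Fast CV fitness for repeated channel-subset evaluations.

    Parameters
    ----------
    features : (trials, channels, samples_per_channel) array
        Preprocessed full-montage feature tensor of the *training* data.
    labels : (trials,) array of +1/-1
    weights : FitnessWeights
    n_folds, fold_seed : CV layout, frozen for the evaluator's lifetime.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        weights: FitnessWeights = FitnessWeights(0.5, 0.5),
        n_folds: int = 10,
        fold_seed: int = 0,
    ) -> None:
        features = np.asarray(features, dtype=np.float64)
        self.labels = np.asarray(labels)
        self.n_channels_total = features.shape[1]
        self.n_per_channel = features.shape[2]
        self.weights = weights
        self.Z = features.reshape(features.shape[0], -1)
        self.folds = make_folds(self.labels, n_folds, fold_seed)
        self.ps = int(np.sum(self.labels == 1))
        self.ns = int(np.sum(self.labels == -1))

        n_full = self.Z.shape[1]
        n_folds = len(self.folds)
        # per-fold full-montage within-class scatter and class-mean difference
        self._S = np.empty((n_folds, n_full, n_full))
        self._mdiff = np.empty((n_folds, n_full))
        for k, (tr, _) in enumerate(self.folds):
            ytr = self.labels[tr]
            pos = self.Z[tr[ytr == 1]]
            neg = self.Z[tr[ytr == -1]]
            if len(pos) < 2 or len(neg) < 2:
                raise ValueError("a CV fold has a near-single-class training set")
            m_pos = pos.mean(axis=0)
            m_neg = neg.mean(axis=0)
            dev_pos = pos - m_pos
            dev_neg = neg - m_neg
            self._S[k] = dev_pos.T @ dev_pos + dev_neg.T @ dev_neg
            self._mdiff[k] = m_pos - m_neg

    def feature_indices(self, channels: tuple[int, ...]) -> np.ndarray:
        ch = np.asarray(channels, dtype=np.intp)
        return (ch[:, None] * self.n_per_channel
                + np.arange(self.n_per_channel)).ravel()

    def evaluate(self, channels, lam: float) -> FitnessResult:
        """CV fitness of one (channel subset, lambda) configuration."""
        channels = tuple(int(c) for c in channels)
        if not channels:
            raise ValueError("channel set is empty")
        idx = self.feature_indices(channels)
        tp = tn = 0
        for k, (tr, te) in enumerate(self.folds):
            S_sub = self._S[k][np.ix_(idx, idx)]
            w = fda.solve_projection(S_sub, self._mdiff[k][idx], lam)
            ytr = self.labels[tr]
            s_tr = self.Z[np.ix_(tr, idx)] @ w
            s_pos = s_tr[ytr == 1]
            s_neg = s_tr[ytr == -1]
            mu_pos, var_pos = s_pos.mean(), s_pos.var(ddof=1)
            mu_neg, var_neg = s_neg.mean(), s_neg.var(ddof=1)
            s_te = self.Z[np.ix_(te, idx)] @ w
            d_pos = (s_te - mu_pos) ** 2 / var_pos
            d_neg = (s_te - mu_neg) ** 2 / var_neg
            pred = np.where(d_pos < d_neg, 1, -1)
            yte = self.labels[te]
            tp += int(np.sum((pred == 1) & (yte == 1)))
            tn += int(np.sum((pred == -1) & (yte == -1)))
        return _result_from_counts(tp, tn, self.ps, self.ns, len(channels),
                                   self.weights, self.n_channels_total)

    def particle_fitness(self, lam: float, channels) -> FitnessResult:
        """Adapter with the (lambda, channels) argument order the swarm uses."""
        return self.evaluate(channels, lam)
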