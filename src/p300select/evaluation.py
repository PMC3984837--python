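"""Validation harness: held-out testing, score averaging, Pareto analysis.

The dataset is split into disjoint train/test halves, stratified so that
every (class, direction, session) combination is represented in both with
the same proportion. The swarm searches on the training half only; a final
FDA classifier is then trained on all training trials with the selected
(lambda, channels) and assessed on the test half by the geometric-mean
accuracy.

Beyond single-trial accuracy, "averaged trials" emulate the classical
noise-reduction trade-off of ERP interfaces: M same-class test trials are
drawn with replacement, their classifier *scores* are averaged, and the
Mahalanobis rule (with the single-trial training statistics) is applied to
the mean score. A fixed seeded master list of index tuples defines every
averaged trial so all configurations are compared on exactly the same
resampled data. Score averaging rather than signal averaging keeps the
training set size intact and is robust to inter-trial latency jitter.

Pareto-front extraction over all (channel count, accuracy) positions the
swarm visited exposes the accuracy/parsimony trade-off boundary, and
selection-frequency maps summarize which channels repeated searches keep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from . import fda
from .datasets import EpochDataset
from .fitness import gm_accuracy
from .preprocessing import PreprocSpec, extract_features, preprocess_dataset

__all__ = [
    "SplitSpec",
    "SplitResult",
    "MasterList",
    "FinalEvaluation",
    "stratified_split",
    "train_final_and_test",
    "build_master_list",
    "averaged_trial_gm",
    "pareto_front",
    "selection_frequency",
    "jaccard",
]


@dataclass(frozen=True)
class SplitSpec:
    fraction_train: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction_train < 1:
            raise ValueError("fraction_train must be in (0, 1)")


class SplitResult(NamedTuple):
    train: EpochDataset
    test: EpochDataset


def stratified_split(dataset: EpochDataset, spec: SplitSpec) -> SplitResult:
    """Disjoint, exhaustive train/test partition stratified by
    (class, direction, session).

    Each stratum splits as evenly as integer rounding allows; odd strata
    alternate which side receives the extra trial so totals stay balanced.
    Deterministic under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    keys = list(zip(dataset.labels, dataset.direction, dataset.session))
    strata: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        strata.setdefault(tuple(int(v) for v in key), []).append(i)

    train_idx: list[int] = []
    test_idx: list[int] = []
    extra_to_train = True
    for key in sorted(strata):
        idx = np.array(strata[key])
        if len(idx) < 2:
            warnings.warn(
                f"stratum {key} has {len(idx)} trial(s); it cannot appear "
                "in both subsets", stacklevel=2,
            )
        perm = idx[rng.permutation(len(idx))]
        n_train = int(np.floor(len(idx) * spec.fraction_train))
        remainder = len(idx) * spec.fraction_train - n_train
        if remainder > 1e-9:  # fractional stratum: alternate the extra trial
            if extra_to_train:
                n_train += 1
            extra_to_train = not extra_to_train
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])

    return SplitResult(
        train=dataset.select(np.sort(train_idx)),
        test=dataset.select(np.sort(test_idx)),
    )


class FinalEvaluation(NamedTuple):
    gm: float
    scores_test: np.ndarray
    model: fda.FDAModel


def train_final_and_test(
    train: EpochDataset,
    test: EpochDataset,
    decoded: tuple[float, Sequence[int]],
    preproc: PreprocSpec,
) -> FinalEvaluation:
    """Fit the final classifier on all training trials; score the test set.

    ``decoded`` is the (lambda, channels) configuration the search
    produced on the training half. Returns the held-out geometric-mean
    accuracy, the raw test scores (needed for score averaging) and the
    fitted model.
    """
    lam, channels = decoded
    channels = tuple(int(c) for c in channels)
    if not channels:
        raise ValueError("channel set is empty")
    overlap = set(train.trial_ids) & set(test.trial_ids)
    if overlap:
        raise ValueError(f"train/test share {len(overlap)} trials")

    Ztr = extract_features(preprocess_dataset(train, preproc), preproc, channels)
    Zte = extract_features(preprocess_dataset(test, preproc), preproc, channels)
    model = fda.fit(Ztr.values, train.labels, lam)
    scores = fda.score_many(model, Zte.values)
    pred = fda.predict_scores(model, scores)
    tp = int(np.sum((pred == 1) & (test.labels == 1)))
    tn = int(np.sum((pred == -1) & (test.labels == -1)))
    gm = gm_accuracy(tp, tn, int(np.sum(test.labels == 1)),
                     int(np.sum(test.labels == -1)))
    return FinalEvaluation(gm=gm, scores_test=scores, model=model)


@dataclass
class MasterList:
    """Frozen composition of averaged trials for each averaging factor M.

    ``entries[M]`` is an (n_tuples, M) array of indices into the
    single-trial test set; ``labels[M]`` the class of each tuple. Every
    tuple is single-class, drawn with replacement, and there are as many
    tuples as single test trials with the identical class ratio (the tuple
    labels mirror the test label sequence). One list is reused across all
    weight cases so comparisons share the same resampled data.
    """

    entries: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]

    @property
    def m_values(self) -> tuple[int, ...]:
        return tuple(sorted(self.entries))


def build_master_list(
    test_labels: np.ndarray,
    m_values: Iterable[int] = range(2, 11),
    seed: int = 0,
) -> MasterList:
    """Seeded master list of same-class index tuples for M = 2..10."""
    test_labels = np.asarray(test_labels)
    pools = {c: np.flatnonzero(test_labels == c) for c in (1, -1)}
    if any(len(p) == 0 for p in pools.values()):
        raise ValueError("both classes must be present in the test set")
    entries: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    children = np.random.SeedSequence(seed).spawn(len(tuple(m_values)))
    for child, m in zip(children, tuple(m_values)):
        if m < 1:
            raise ValueError("M must be >= 1")
        rng = np.random.default_rng(child)
        idx = np.empty((len(test_labels), m), dtype=np.int64)
        for i, lab in enumerate(test_labels):
            idx[i] = rng.choice(pools[int(lab)], size=m, replace=True)
        entries[m] = idx
        labels[m] = test_labels.copy()
    return MasterList(entries=entries, labels=labels)


def averaged_trial_gm(
    scores_test: np.ndarray,
    test_labels: np.ndarray,
    model: fda.FDAModel,
    master: MasterList,
    m: int,
) -> float:
    """Geometric-mean accuracy of M-averaged trials.

    Each averaged trial's score is the mean of its members' single-trial
    scores; classification applies the Mahalanobis rule with the
    *single-trial* training statistics (no averaged-trial training set
    exists in this procedure).
    """
    if m not in master.entries:
        raise ValueError(f"M = {m} not in master list {master.m_values}")
    scores_test = np.asarray(scores_test, dtype=np.float64)
    idx = master.entries[m]
    labels = master.labels[m]
    mean_scores = scores_test[idx].mean(axis=1)
    pred = fda.predict_scores(model, mean_scores)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == -1) & (labels == -1)))
    return gm_accuracy(tp, tn, int(np.sum(labels == 1)), int(np.sum(labels == -1)))


def pareto_front(points: Iterable[tuple[int, float]]) -> list[tuple[int, float]]:
    """Non-dominated (n_channels, accuracy) points: maximize accuracy,
    minimize channels.

    A point survives iff no other point is at least as accurate with at
    most as many channels and strictly better in one of the two. Returns
    the unique survivors sorted by channel count (accuracy then strictly
    increases with channel count along the front).
    """
    pts = sorted(set((int(n), float(acc)) for n, acc in points))
    if not pts:
        raise ValueError("no points given")
    # keep only the best accuracy at each channel count, then sweep
    best_at: dict[int, float] = {}
    for n, acc in pts:
        if n not in best_at or acc > best_at[n]:
            best_at[n] = acc
    front: list[tuple[int, float]] = []
    best_acc = -np.inf
    for n in sorted(best_at):
        if best_at[n] > best_acc:
            front.append((n, best_at[n]))
            best_acc = best_at[n]
    return front


def selection_frequency(
    results: Sequence, n_channels_total: int
) -> np.ndarray:
    """Fraction of search results whose gbest includes each channel."""
    if len(results) == 0:
        raise ValueError("no results given")
    freq = np.zeros(n_channels_total)
    for res in results:
        if res.decoded is None:
            raise ValueError("a result has no feasible gbest")
        _, channels = res.decoded
        freq[list(channels)] += 1.0
    return freq / len(results)


def jaccard(a: Iterable[int], b: Iterable[int]) -> float:
    """Jaccard overlap |a & b| / |a | b| between two channel sets."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
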