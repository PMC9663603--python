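"""Pairwise condition decoding over time with pseudo-trial averaging.

For each timepoint and condition pair, the M raw trials of each condition
are randomly partitioned into groups of k and sub-averaged into L = M/k
pseudo-trials (boosting SNR); a linear SVM is trained on L-1 pseudo-trials
per condition and tested on the held-out pseudo-trial of each condition.
Regrouping and hold-out are re-randomized ``n_iterations`` times and the
accuracy averaged, yielding a time x condition-pair accuracy matrix in
percent with chance at 50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.svm import SVC

from .synth import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "DecodingConfig",
    "DecodingMatrixTimecourse",
    "make_pseudotrials",
    "decode_pair",
    "decode_all_pairs",
]


@dataclass
class DecodingConfig:
    """k=5 sub-averaging with 100 random regroupings, as in the study."""

    k: int = 5
    n_iterations: int = 100
    svm_regularization: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.svm_regularization <= 0:
            raise ValueError("svm_regularization must be positive")


@dataclass
class DecodingMatrixTimecourse:
    timepoints: np.ndarray
    pair_labels: list[tuple[str, str]]
    accuracies: np.ndarray  # (n_timepoints, n_pairs), percent

    def mean_curve(self) -> np.ndarray:
        """Grand-mean decoding curve: arithmetic mean over condition pairs."""
        return self.accuracies.mean(axis=1)


def make_pseudotrials(trials: np.ndarray, k: int, seed: int | np.random.Generator) -> np.ndarray:
    """Randomly partition M trials into groups of k and average each group.

    Returns L = floor(M/k) pseudo-trial patterns; remainder trials are
    dropped (re-randomized assignments mean all trials are used in
    expectation across iterations).
    """
    trials = np.asarray(trials, dtype=float)
    m = trials.shape[0]
    if k > m:
        raise ValueError(f"k={k} exceeds trial count M={m}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(m)
    n_used = (m // k) * k
    if n_used < m:
        logger.warning("dropping %d remainder trial(s) (M=%d, k=%d)", m - n_used, m, k)
    groups = perm[:n_used].reshape(m // k, k)
    return trials[groups].mean(axis=1)


def _accuracy_timecourse(a: np.ndarray, b: np.ndarray, config: DecodingConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Mean leave-one-pseudo-trial-out SVM accuracy per timepoint (percent)."""
    m = a.shape[0]
    l = m // config.k
    if l < 2:
        raise ValueError(f"L = M//k = {l} < 2: no train/test split possible")
    n_t = a.shape[2]
    correct = np.zeros(n_t)
    labels = np.concatenate([np.zeros(l - 1), np.ones(l - 1)])
    for _ in range(config.n_iterations):
        # one partition shared by both conditions: makes the accuracy exactly
        # invariant under swapping the condition labels
        groups = rng.permutation(m)[: l * config.k].reshape(l, config.k)
        pa = a[groups].mean(axis=1)  # (L, channels, time)
        pb = b[groups].mean(axis=1)
        held = rng.integers(l)  # held-out pseudo-trial index, re-randomized
        train_idx = np.delete(np.arange(l), held)
        for t in range(n_t):
            x_train = np.concatenate([pa[train_idx, :, t], pb[train_idx, :, t]])
            clf = SVC(kernel="linear", C=config.svm_regularization)
            clf.fit(x_train, labels)
            scores = clf.decision_function(np.stack([pa[held, :, t], pb[held, :, t]]))
            # decision exactly on the boundary counts as incorrect
            correct[t] += int(scores[0] < 0) + int(scores[1] > 0)
    return 100.0 * correct / (2 * config.n_iterations)


def decode_pair(epochs_a: np.ndarray, epochs_b: np.ndarray, config: DecodingConfig) -> np.ndarray:
    """Decoding accuracy per timepoint for one condition pair.

    ``epochs_a``/``epochs_b`` are (M, channels, time) trial arrays with equal
    M and matching channels/timepoints.
    """
    a = np.asarray(epochs_a, dtype=float)
    b = np.asarray(epochs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must share M, channels and timepoints")
    rng = np.random.default_rng(config.seed)
    return _accuracy_timecourse(a, b, config, rng)


def decode_all_pairs(epochs: EpochSet, config: DecodingConfig) -> DecodingMatrixTimecourse:
    """Pairwise decoding for every unordered condition pair."""
    n_cond = len(epochs.conditions)
    if n_cond < 2:
        raise ValueError("need at least 2 conditions")
    pairs = list(combinations(range(n_cond), 2))
    n_t = epochs.timepoints.size
    acc = np.empty((n_t, len(pairs)))
    root = np.random.default_rng(config.seed)
    for p, (i, j) in enumerate(pairs):
        rng = np.random.default_rng(root.integers(2**31))
        try:
            acc[:, p] = _accuracy_timecourse(epochs.data[i], epochs.data[j], config, rng)
        except ValueError as err:
            raise ValueError(
                f"pair ({epochs.conditions[i]}, {epochs.conditions[j]}): {err}"
            ) from err
    labels = [(epochs.conditions[i], epochs.conditions[j]) for i, j in pairs]
    return DecodingMatrixTimecourse(
        timepoints=epochs.timepoints, pair_labels=labels, accuracies=acc
    )
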