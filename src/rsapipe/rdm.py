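"""Representational dissimilarity matrices and their comparison.

An RDM is the universal currency between pipeline stages: a square symmetric
matrix of pairwise dissimilarities between stimulus response patterns with a
zero diagonal.  This module builds RDMs from response patterns (Euclidean
distance) and from single rating dimensions (absolute mean-rating
difference), vectorizes them (row-major upper triangle, shared by every
module), compares model to data RDMs by Spearman rank correlation, and
computes the upper/lower noise ceiling bracketing the best correlation any
true model could achieve given between-subject variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr

from .synth import RatingCatalog, SubjectRDMStack

__all__ = [
    "RDM",
    "ModelRDMSet",
    "RSAResult",
    "rdm_from_patterns",
    "model_rdm_from_dimension",
    "vectorize",
    "compare_spearman",
    "rsa",
    "noise_ceiling",
    "between_participant_consistency",
    "within_participant_consistency",
]


@dataclass
class RDM:
    """Square symmetric nonnegative dissimilarity matrix, zero diagonal."""

    stimulus_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.stimulus_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if np.any(self.values < -1e-10):
            raise ValueError("dissimilarities must be nonnegative")

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)


@dataclass
class ModelRDMSet:
    """Named model RDMs over a shared stimulus ordering."""

    rdms: dict[str, RDM]

    def __post_init__(self) -> None:
        names = list(self.rdms)
        if len(set(names)) != len(names):
            raise ValueError("model names must be unique")
        orderings = {tuple(r.stimulus_ids) for r in self.rdms.values()}
        if len(orderings) > 1:
            raise ValueError("all model RDMs must share the stimulus ordering")

    @property
    def names(self) -> list[str]:
        return list(self.rdms)

    def design_matrix(self) -> np.ndarray:
        """Vectorized models stacked as columns, shape (n_pairs, n_models)."""
        return np.column_stack([vectorize(r) for r in self.rdms.values()])


@dataclass
class RSAResult:
    """Per-subject, per-model Spearman rho with group summary."""

    model_names: list[str]
    subject_ids: list[str]
    rho: np.ndarray  # (n_subjects, n_models)
    noise_ceiling: tuple[float, float] | None = None

    def group_mean(self) -> np.ndarray:
        return np.nanmean(self.rho, axis=0)


def rdm_from_patterns(patterns: np.ndarray, stimulus_ids: list[str] | None = None) -> RDM:
    """Euclidean-distance RDM from a stimulus x feature pattern matrix."""
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[0] < 2:
        raise ValueError("need at least 2 stimuli")
    if not np.all(np.isfinite(patterns)):
        bad = np.where(~np.all(np.isfinite(patterns), axis=1))[0]
        ids = stimulus_ids or [str(i) for i in range(patterns.shape[0])]
        raise ValueError(f"missing values in patterns for stimuli: {[ids[i] for i in bad]}")
    values = squareform(pdist(patterns, metric="euclidean"))
    if stimulus_ids is None:
        stimulus_ids = [f"stim{i:04d}" for i in range(patterns.shape[0])]
    return RDM(stimulus_ids=stimulus_ids, values=values)


def model_rdm_from_dimension(catalog: RatingCatalog, dimension_name: str) -> RDM:
    """Single-dimension model RDM: |mean rating(i) - mean rating(j)|."""
    if dimension_name not in catalog.dimension_names:
        raise ValueError(
            f"unknown dimension {dimension_name!r}; have {catalog.dimension_names}"
        )
    d = catalog.dimension_names.index(dimension_name)
    mean = catalog.mean_ratings()[:, d]
    values = np.abs(mean[:, None] - mean[None, :])
    return RDM(stimulus_ids=list(catalog.stimulus_ids), values=values)


def vectorize(rdm: RDM | np.ndarray) -> np.ndarray:
    """Row-major upper triangle (diagonal excluded), length n(n-1)/2."""
    values = rdm.values if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    return values[np.triu_indices(values.shape[0], k=1)]


def compare_spearman(model: RDM, data: RDM) -> float:
    """Spearman rank correlation of vectorized RDMs (average-rank ties)."""
    if model.stimulus_ids != data.stimulus_ids:
        raise ValueError("model and data RDMs must share stimulus ordering")
    mv, dv = vectorize(model), vectorize(data)
    if np.ptp(mv) == 0 or np.ptp(dv) == 0:
        warnings.warn("constant RDM vector: Spearman rho undefined", stacklevel=2)
        return np.nan
    rho, _ = spearmanr(mv, dv)
    return float(rho)


def rsa(models: ModelRDMSet, stack: SubjectRDMStack) -> RSAResult:
    """Correlate each model RDM with each subject's data RDM."""
    names = models.names
    rho = np.empty((stack.n_subjects, len(names)))
    for s in range(stack.n_subjects):
        data = RDM(stimulus_ids=list(stack.stimulus_ids), values=stack.rdms[s])
        for m, name in enumerate(names):
            rho[s, m] = compare_spearman(models.rdms[name], data)
    nc = noise_ceiling(stack) if stack.n_subjects >= 2 else None
    return RSAResult(
        model_names=names,
        subject_ids=list(stack.subject_ids),
        rho=rho,
        noise_ceiling=nc,
    )


def noise_ceiling(stack: SubjectRDMStack) -> tuple[float, float]:
    """Upper/lower noise ceiling for Spearman RSA.

    RDM vectors are rank-transformed first (matching the Spearman inference
    they bound).  The upper bound correlates each subject with the group mean
    including that subject (optimistic); the lower bound with the
    leave-one-subject-out mean (pessimistic).
    """
    if stack.n_subjects < 2:
        raise ValueError("noise ceiling needs at least 2 subjects")
    iu = np.triu_indices(stack.rdms.shape[1], k=1)
    vecs = stack.rdms[:, iu[0], iu[1]]
    ranked = np.apply_along_axis(rankdata, 1, vecs)
    n = ranked.shape[0]
    total = ranked.sum(axis=0)
    upper_r, lower_r = [], []
    for s in range(n):
        mean_all = total / n
        mean_loo = (total - ranked[s]) / (n - 1)
        upper_r.append(spearmanr(ranked[s], mean_all)[0])
        lower_r.append(spearmanr(ranked[s], mean_loo)[0])
    return float(np.mean(lower_r)), float(np.mean(upper_r))


def between_participant_consistency(catalog: RatingCatalog) -> float:
    """Mean pairwise Pearson r between participants' full rating vectors."""
    if catalog.n_participants < 2:
        raise ValueError("need at least 2 participants")
    flat = catalog.ratings.reshape(catalog.n_participants, -1)
    rs = []
    for i in range(catalog.n_participants):
        for j in range(i + 1, catalog.n_participants):
            if np.ptp(flat[i]) == 0 or np.ptp(flat[j]) == 0:
                warnings.warn(
                    f"constant rating vector for participant pair ({i},{j}); skipped",
                    stacklevel=2,
                )
                continue
            rs.append(np.corrcoef(flat[i], flat[j])[0, 1])
    return float(np.mean(rs))


def within_participant_consistency(catalog: RatingCatalog) -> float:
    """Mean per-participant Pearson r between first and repeated ratings."""
    if not catalog.repeat_ids or catalog.repeat_ratings is None:
        raise ValueError("catalog has no repeated presentations")
    idx = [catalog.stimulus_ids.index(s) for s in catalog.repeat_ids]
    if len(idx) < 2:
        raise ValueError("need at least 2 repeated stimuli to correlate")
    first = catalog.ratings[:, idx, :].reshape(catalog.n_participants, -1)
    second = catalog.repeat_ratings.reshape(catalog.n_participants, -1)
    rs = [np.corrcoef(first[p], second[p])[0, 1] for p in range(catalog.n_participants)]
    return float(np.mean(rs))
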