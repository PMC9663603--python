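"""Unique-variance partitioning via nested non-negative least squares.

A data dissimilarity vector is regressed on model dissimilarity vectors with
non-negative weights and a free intercept.  The unique variance of model m is
the drop in R^2 when m is removed from the predictor set:
``u_m = R^2_full - R^2_reduced(-m)``, always nonnegative because the reduced
feasible set is nested in the full one.  Nuisance predictors (e.g. a
low-level visual feature RDM) can be held in both the full and every reduced
fit so each model's unique variance is assessed over and above them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .rdm import RDM, ModelRDMSet, vectorize

logger = logging.getLogger(__name__)

__all__ = [
    "VariancePartition",
    "nnls_fit",
    "partition_unique",
    "partition_with_nuisance",
    "partition_per_subject",
]


@dataclass
class VariancePartition:
    r2_full: float
    unique: dict[str, float]
    weights_full: np.ndarray  # model weights then intercept


def nnls_fit(
    predictors: np.ndarray,
    response: np.ndarray,
    include_intercept: bool = True,
    standardize: bool = True,
) -> tuple[np.ndarray, float]:
    """Least squares with nonnegative predictor weights and free intercept.

    With ``include_intercept`` the intercept is profiled out by centering
    (its optimum given the weights is the mean residual), leaving a pure NNLS
    problem on centered data.  ``standardize`` scales predictors to unit
    variance first so arbitrary model-RDM scaling cannot masquerade as
    explained variance; weights are reported on the original scale.

    Returns ``(weights_with_intercept, r2)`` where R^2 about the response
    mean is floored at 0 (a constrained fit can do worse than the mean).
    """
    x = np.atleast_2d(np.asarray(predictors, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and np.asarray(response).size == x.shape[1]:
        x = x.T
    y = np.asarray(response, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("predictors and response must be aligned")
    if x.shape[1] < 1:
        raise ValueError("need at least one predictor")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        logger.warning("zero-variance response: R^2 undefined")
        return np.full(x.shape[1] + 1, np.nan), np.nan

    scales = np.ones(x.shape[1])
    if standardize:
        sd = x.std(axis=0)
        scales = np.where(sd > 0, sd, 1.0)
    xs = x / scales

    if include_intercept:
        xc = xs - xs.mean(axis=0)
        yc = y - y.mean()
        w_scaled, _ = _scipy_nnls(xc, yc)
        intercept = float(y.mean() - xs.mean(axis=0) @ w_scaled)
    else:
        w_scaled, _ = _scipy_nnls(xs, y)
        intercept = 0.0

    resid = y - (xs @ w_scaled + intercept)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if r2 < 0:
        logger.info("negative explained variance %.3g floored at 0", r2)
        r2 = 0.0
    weights = np.append(w_scaled / scales, intercept)
    return weights, r2


def _partition(design: np.ndarray, names: list[str], y: np.ndarray, n_keep: int) -> VariancePartition:
    """Shared full-vs-reduced machinery; the first ``n_keep`` columns are the
    models of interest, any remaining columns are always-present nuisance."""
    weights, r2_full = nnls_fit(design, y)
    unique: dict[str, float] = {}
    for m in range(n_keep):
        reduced = np.delete(design, m, axis=1)
        if reduced.shape[1] == 0:
            r2_reduced = 0.0  # intercept-only fit explains nothing about the mean
        else:
            _, r2_reduced = nnls_fit(reduced, y)
        unique[names[m]] = max(r2_full - r2_reduced, 0.0)
    return VariancePartition(r2_full=r2_full, unique=unique, weights_full=weights)


def partition_unique(models: ModelRDMSet, data: RDM) -> VariancePartition:
    """Per-model unique variance of ``data`` explained by the model set."""
    if len(models.rdms) < 1:
        raise ValueError("need at least one model")
    names = models.names
    design = models.design_matrix()
    y = vectorize(data)
    if design.shape[0] != y.size:
        raise ValueError("models and data must share stimulus ordering")
    return _partition(design, names, y, n_keep=len(names))


def partition_with_nuisance(
    models: ModelRDMSet, nuisance_models: ModelRDMSet, data: RDM
) -> VariancePartition:
    """Unique variance per model with nuisance predictors always present.

    Nuisance predictors sit in both the full and every reduced design, so
    ``u_m`` measures what model m explains over and above them.
    """
    names = models.names
    nuis_names = nuisance_models.names
    for nn in nuis_names:
        nv = vectorize(nuisance_models.rdms[nn])
        for mn in names:
            if np.allclose(nv, vectorize(models.rdms[mn])):
                raise ValueError(f"nuisance {nn!r} identical to model {mn!r}")
    design = np.column_stack([models.design_matrix(), nuisance_models.design_matrix()])
    y = vectorize(data)
    if design.shape[0] != y.size:
        raise ValueError("models and data must share stimulus ordering")
    return _partition(design, names + nuis_names, y, n_keep=len(names))


def partition_per_subject(models: ModelRDMSet, stack) -> list[VariancePartition]:
    """Apply :func:`partition_unique` to every subject RDM in a stack."""
    out = []
    for s in range(stack.n_subjects):
        data = RDM(stimulus_ids=list(stack.stimulus_ids), values=stack.rdms[s])
        out.append(partition_unique(models, data))
    return out
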