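"""ROI voxel selection and volume-based searchlight RSA.

ROIs keep the ``n_top`` most strongly activated voxels inside an anatomical
mask.  The searchlight slides a sphere (Euclidean radius in voxel units on
the integer grid) over every in-mask voxel, computes the Euclidean RDM of the
neighbourhood's condition x voxel patterns and correlates it (Spearman) with
a model RDM, yielding a per-subject correlation map for voxelwise group
inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .rdm import RDM, vectorize
from .synth import VolumeResponses

logger = logging.getLogger(__name__)

__all__ = [
    "ROIDefinition",
    "SearchlightMap",
    "select_roi_top_voxels",
    "sphere_neighbourhood",
    "sphere_offsets",
    "searchlight_rsa",
]


@dataclass
class ROIDefinition:
    name: str
    voxel_indices: np.ndarray  # linear indices into the flattened grid
    n_top: int


@dataclass
class SearchlightMap:
    grid_shape: tuple[int, int, int]
    radius: float
    rho: np.ndarray  # flattened per-voxel model correlation; NaN outside mask


def select_roi_top_voxels(
    activation_map: np.ndarray,
    roi_mask: np.ndarray,
    n_top: int = 100,
    name: str = "roi",
) -> ROIDefinition:
    """The ``n_top`` most activated voxels within a mask.

    Ties at the cutoff are broken by ascending linear voxel index; a mask
    smaller than ``n_top`` returns all its voxels with a warning.
    """
    activation = np.asarray(activation_map, dtype=float).ravel()
    mask = np.asarray(roi_mask, dtype=bool).ravel()
    if not mask.any():
        raise ValueError("empty ROI mask")
    candidates = np.where(mask)[0]
    if candidates.size <= n_top:
        if candidates.size < n_top:
            logger.warning(
                "mask has %d voxels < n_top=%d: returning all", candidates.size, n_top
            )
        chosen = candidates
    else:
        # sort by (-activation, linear index): deterministic tie-break
        order = np.lexsort((candidates, -activation[candidates]))
        chosen = np.sort(candidates[order[:n_top]])
    return ROIDefinition(name=name, voxel_indices=np.sort(chosen), n_top=n_top)


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets (dz,dy,dx) with squared Euclidean norm <= radius^2."""
    r = int(np.floor(radius))
    g = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(g, g, g, indexing="ij")
    keep = dz**2 + dy**2 + dx**2 <= radius**2
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1)


def sphere_neighbourhood(
    center: tuple[int, int, int],
    radius: float,
    mask: np.ndarray,
    grid_shape: tuple[int, int, int],
) -> np.ndarray:
    """Linear indices of in-mask voxels within Euclidean ``radius`` of center."""
    mask = np.asarray(mask, dtype=bool).reshape(grid_shape)
    center = tuple(int(c) for c in center)
    if not mask[center]:
        raise ValueError(f"center {center} outside mask")
    coords = np.asarray(center) + sphere_offsets(radius)
    in_grid = np.all((coords >= 0) & (coords < np.asarray(grid_shape)), axis=1)
    coords = coords[in_grid]
    linear = np.ravel_multi_index(coords.T, grid_shape)
    return np.sort(linear[mask.ravel()[linear]])


def searchlight_rsa(volume: VolumeResponses, model: RDM, radius: float = 4.0) -> SearchlightMap:
    """Spearman correlation of each searchlight's Euclidean RDM with a model.

    Centers whose neighbourhood holds fewer than 2 voxels are skipped (NaN)
    with a warning; a constant model RDM yields an all-NaN map.
    """
    n_cond = volume.n_conditions
    if model.n_stimuli != n_cond:
        raise ValueError(
            f"model RDM over {model.n_stimuli} stimuli but volume has {n_cond} conditions"
        )
    model_vec = vectorize(model)
    rho_map = np.full(int(np.prod(volume.grid_shape)), np.nan)
    if np.ptp(model_vec) == 0:
        logger.warning("constant model RDM: searchlight correlations undefined")
        return SearchlightMap(grid_shape=volume.grid_shape, radius=radius, rho=rho_map)
    model_rank = rankdata(model_vec)
    model_rank = model_rank - model_rank.mean()
    model_norm = np.sqrt(np.sum(model_rank**2))

    mask3 = volume.mask.reshape(volume.grid_shape)
    offsets = sphere_offsets(radius)
    shape_arr = np.asarray(volume.grid_shape)
    flat_mask = volume.mask
    for center in np.argwhere(mask3):
        coords = center + offsets
        ok = np.all((coords >= 0) & (coords < shape_arr), axis=1)
        linear = np.ravel_multi_index(coords[ok].T, volume.grid_shape)
        linear = linear[flat_mask[linear]]
        if linear.size < 2:
            logger.warning("searchlight at %s has <2 voxels: skipped", tuple(center))
            continue
        patterns = volume.responses[linear].T  # condition x voxel
        d = pdist(patterns, metric="euclidean")
        if np.ptp(d) == 0:
            continue
        dr = rankdata(d)
        dr = dr - dr.mean()
        denom = model_norm * np.sqrt(np.sum(dr**2))
        c = int(np.ravel_multi_index(center, volume.grid_shape))
        rho_map[c] = float(np.dot(model_rank, dr) / denom)
    return SearchlightMap(grid_shape=volume.grid_shape, radius=radius, rho=rho_map)
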