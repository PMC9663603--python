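"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline (stimulus selection, RSA, unique
variance, decoding, searchlight) is exercised against data produced here, so
each generator plants a known structure that the corresponding analysis must
recover:

* ``gen_rating_catalog`` — multi-participant rating tables with a requested
  inter-dimension correlation matrix,
* ``gen_subject_rdm_stack`` — per-subject RDMs as non-negative mixtures of
  model RDMs plus noise,
* ``gen_epochs`` — multichannel epoch sets with condition separability
  confined to a time window,
* ``gen_voxel_volume`` — 3-D voxel volumes whose within-region response
  geometry is an isometric embedding of a given model RDM.

All randomness flows through an explicit per-call seed; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_DIMENSIONS",
    "RatingCatalog",
    "SubjectRDMStack",
    "EpochSet",
    "VolumeResponses",
    "SimSpec",
    "gen_rating_catalog",
    "gen_subject_rdm_stack",
    "gen_epochs",
    "gen_voxel_volume",
]

#: The five rated object dimensions of animacy.
DEFAULT_DIMENSIONS = (
    "being alive",
    "looking like an animal",
    "having agency",
    "having mobility",
    "being unpredictable",
)

RATING_MIN = -10.0
RATING_MAX = 10.0

# Latent dimension scores have unit variance; this affine scale maps them
# onto the rating scale so that ~3 sd span the half-range and clipping at
# the +/-10 bounds is rare.
_LATENT_SCALE = RATING_MAX / 3.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RatingCatalog:
    """Stimuli x dimensions x participants ratings with category labels.

    ``ratings`` has shape (n_participants, n_stimuli, n_dims), each value a
    rating point on the continuous -10..+10 scale.  ``repeat_ids`` /
    ``repeat_ratings`` hold second presentations of a subset of stimuli for
    within-participant consistency estimation.
    """

    stimulus_ids: list[str]
    category_labels: list[str]
    dimension_names: list[str]
    ratings: np.ndarray
    repeat_ids: list[str] = field(default_factory=list)
    repeat_ratings: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.ratings.ndim != 3:
            raise ValueError("ratings must be participants x stimuli x dimensions")
        n_part, n_stim, n_dim = self.ratings.shape
        if len(self.stimulus_ids) != n_stim:
            raise ValueError("stimulus_ids length mismatch with ratings")
        if len(self.category_labels) != n_stim:
            raise ValueError("every stimulus needs exactly one category label")
        if len(self.dimension_names) != n_dim:
            raise ValueError("dimension_names length mismatch with ratings")
        if len(set(self.dimension_names)) != n_dim:
            raise ValueError("dimension_names must be unique")
        if np.any(self.ratings < RATING_MIN) or np.any(self.ratings > RATING_MAX):
            raise ValueError("ratings must lie within [-10, +10]")

    @property
    def n_participants(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.ratings.shape[1]

    @property
    def n_dims(self) -> int:
        return self.ratings.shape[2]

    def mean_ratings(self) -> np.ndarray:
        """Participant-mean ratings, shape (n_stimuli, n_dims)."""
        return self.ratings.mean(axis=0)


@dataclass
class SubjectRDMStack:
    """One RDM per subject over a common stimulus ordering."""

    subject_ids: list[str]
    stimulus_ids: list[str]
    rdms: np.ndarray  # (n_subjects, n_stimuli, n_stimuli)

    def __post_init__(self) -> None:
        self.rdms = np.asarray(self.rdms, dtype=float)
        if self.rdms.ndim != 3 or self.rdms.shape[1] != self.rdms.shape[2]:
            raise ValueError("rdms must be subjects x n x n")
        if len(self.subject_ids) != self.rdms.shape[0]:
            raise ValueError("subject_ids length mismatch")
        if len(self.stimulus_ids) != self.rdms.shape[1]:
            raise ValueError("stimulus_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.rdms.shape[0]


@dataclass
class EpochSet:
    """Multichannel epochs: condition x trial x channel x time."""

    conditions: list[str]
    timepoints: np.ndarray  # ms relative to stimulus onset
    data: np.ndarray  # (n_conditions, M, n_channels, n_timepoints)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be condition x trial x channel x time")
        if len(self.conditions) != self.data.shape[0]:
            raise ValueError("conditions length mismatch")
        if len(self.timepoints) != self.data.shape[3]:
            raise ValueError("timepoints length mismatch")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")

    @property
    def trials_per_condition(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]


@dataclass
class VolumeResponses:
    """Voxel responses on a 3-D grid.

    ``responses`` is (n_voxels, n_conditions) in t-value-like units with rows
    aligned to the flattened (C-order) grid; entries outside ``mask`` are 0.
    ``activation_map`` is a per-voxel overall-activation scalar.
    """

    grid_shape: tuple[int, int, int]
    mask: np.ndarray  # bool, flattened length prod(grid_shape)
    responses: np.ndarray  # (n_voxels, n_conditions)
    activation_map: np.ndarray  # (n_voxels,)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool).ravel()
        self.responses = np.asarray(self.responses, dtype=float)
        self.activation_map = np.asarray(self.activation_map, dtype=float).ravel()
        n_vox = int(np.prod(self.grid_shape))
        if self.mask.size != n_vox:
            raise ValueError("mask size must equal prod(grid_shape)")
        if self.responses.shape[0] != n_vox:
            raise ValueError("responses must have one row per voxel")
        if self.activation_map.size != n_vox:
            raise ValueError("activation_map must align to the grid")
        if np.any(self.responses[~self.mask] != 0):
            raise ValueError("responses defined only where mask is true")

    @property
    def n_conditions(self) -> int:
        return self.responses.shape[1]


@dataclass
class SimSpec:
    """Parameters shared by the generators.

    Defaults reproduce the study conditions: 300 candidate stimuli rated on
    five dimensions by 26 participants with 30 repeats; 19 subjects; epochs
    with M=30 trials on 64 channels sampled every 1 ms from -100 to 1000 ms
    with the condition effect confined to a window.  ``noise_sd`` is rating
    noise in rating points for the catalog generator and signal-unit noise
    elsewhere.
    """

    seed: int = 0
    n_stimuli: int = 300
    n_dims: int = 5
    n_participants: int = 26
    target_corr: np.ndarray | None = None  # default: identity
    noise_sd: float = 1.43
    stable_bias_sd: float = 2.32
    n_categories: int = 100
    n_repeats: int = 30
    dimension_names: tuple[str, ...] | None = None
    # epoch generation
    n_conditions: int = 128
    trials_per_condition: int = 30
    n_channels: int = 64
    timepoints: np.ndarray | None = None  # default: -100..1000 ms step 1
    effect_window_ms: tuple[float, float] = (50.0, 500.0)
    effect_size: float = 1.0
    # volume generation
    grid_shape: tuple[int, int, int] = (20, 20, 20)

    def validate_corr(self) -> np.ndarray:
        """Return the target correlation matrix, checking PSD-ness."""
        if self.target_corr is None:
            return np.eye(self.n_dims)
        corr = np.asarray(self.target_corr, dtype=float)
        if corr.shape != (self.n_dims, self.n_dims):
            raise ValueError(
                f"target_corr must be {self.n_dims}x{self.n_dims}, got {corr.shape}"
            )
        if not np.allclose(corr, corr.T):
            raise ValueError(f"target_corr is not symmetric:\n{corr}")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError(f"target_corr must have unit diagonal:\n{corr}")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ValueError(
                f"target_corr is not positive semidefinite "
                f"(min eigenvalue {eigvals.min():.3g}):\n{corr}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        return corr


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_rating_catalog(spec: SimSpec) -> RatingCatalog:
    """Generate a rating catalog with a planted inter-dimension correlation.

    Latent per-stimulus dimension scores are drawn from a multivariate normal
    with the requested correlation matrix, affinely mapped onto the -10..+10
    rating scale.  Each participant's rating is latent + a stable
    participant-specific judgement bias (``stable_bias_sd``, shared between
    repeated presentations of a stimulus) + fresh presentation noise
    (``noise_sd``), clipped at the scale bounds.  The stable bias makes
    within-participant consistency exceed between-participant consistency,
    as for human raters; the defaults put them near 0.89 and 0.6.  Category
    labels are assigned round-robin over ``spec.n_categories`` categories;
    the first two categories are tagged "human face" and "human body" so
    inclusion constraints of the stimulus-selection stage are exercisable.
    """
    corr = spec.validate_corr()
    rng = np.random.default_rng(spec.seed)

    # correlated latents via eigen-decomposition (tolerates PSD-singular corr)
    eigvals, eigvecs = np.linalg.eigh(corr)
    transform = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0, None)))
    latent = rng.standard_normal((spec.n_stimuli, spec.n_dims)) @ transform.T
    latent = np.clip(latent * _LATENT_SCALE, RATING_MIN, RATING_MAX)

    shape = (spec.n_participants, spec.n_stimuli, spec.n_dims)
    bias = rng.normal(0.0, spec.stable_bias_sd, size=shape)
    noise = rng.normal(0.0, spec.noise_sd, size=shape)
    ratings = np.clip(latent[None, :, :] + bias + noise, RATING_MIN, RATING_MAX)

    stimulus_ids = [f"stim{i:04d}" for i in range(spec.n_stimuli)]
    categories = []
    for i in range(spec.n_stimuli):
        c = i % spec.n_categories
        if c == 0:
            categories.append("human face")
        elif c == 1:
            categories.append("human body")
        else:
            categories.append(f"category{c:03d}")

    dims = list(spec.dimension_names) if spec.dimension_names is not None else list(
        DEFAULT_DIMENSIONS[: spec.n_dims]
        if spec.n_dims <= len(DEFAULT_DIMENSIONS)
        else [f"dim{i}" for i in range(spec.n_dims)]
    )

    n_rep = min(spec.n_repeats, spec.n_stimuli)
    repeat_ids: list[str] = []
    repeat_ratings = None
    if n_rep >= 1:
        rep_idx = rng.choice(spec.n_stimuli, size=n_rep, replace=False)
        repeat_ids = [stimulus_ids[i] for i in rep_idx]
        rep_noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_participants, n_rep, spec.n_dims))
        repeat_ratings = np.clip(
            latent[rep_idx][None, :, :] + bias[:, rep_idx, :] + rep_noise,
            RATING_MIN, RATING_MAX,
        )

    return RatingCatalog(
        stimulus_ids=stimulus_ids,
        category_labels=categories,
        dimension_names=dims,
        ratings=ratings,
        repeat_ids=repeat_ids,
        repeat_ratings=repeat_ratings,
    )


def gen_subject_rdm_stack(
    model_rdms: list[np.ndarray],
    weights,
    noise_sd: float,
    n_subjects: int,
    seed: int,
    stimulus_ids: list[str] | None = None,
) -> SubjectRDMStack:
    """Subject RDMs as a non-negative mixture of model RDMs plus noise.

    Each subject RDM is ``sum_i w_i * model_i`` plus symmetric zero-diagonal
    Gaussian noise applied on the vectorized upper triangle and mirrored;
    negative dissimilarities are clipped to 0.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative (non-negative mixture)")
    if len(model_rdms) != weights.size:
        raise ValueError("one weight per model RDM required")
    models = [np.asarray(m, dtype=float) for m in model_rdms]
    n = models[0].shape[0]
    for m in models:
        if m.shape != (n, n):
            raise ValueError("model RDMs must share stimulus ordering and size")

    base = sum(w * m for w, m in zip(weights, models))
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    rdms = np.empty((n_subjects, n, n))
    for s in range(n_subjects):
        noisy = np.zeros((n, n))
        vec = base[iu] + rng.normal(0.0, noise_sd, size=iu[0].size)
        noisy[iu] = vec
        noisy += noisy.T
        rdms[s] = np.clip(noisy, 0.0, None)

    if stimulus_ids is None:
        stimulus_ids = [f"stim{i:04d}" for i in range(n)]
    subject_ids = [f"sub{s:02d}" for s in range(n_subjects)]
    return SubjectRDMStack(subject_ids=subject_ids, stimulus_ids=stimulus_ids, rdms=rdms)


def gen_epochs(spec: SimSpec) -> EpochSet:
    """Generate epochs whose condition means differ only inside a window.

    Each condition gets a fixed random channel-mean pattern scaled by
    ``effect_size``; the pattern is added to trial noise only at timepoints
    inside ``effect_window_ms``.  Outside the window all conditions share the
    zero mean, so pairwise decoding is at chance there by construction.
    """
    if spec.trials_per_condition <= 0:
        raise ValueError("trials_per_condition (M) must be positive")
    t = (
        np.asarray(spec.timepoints, dtype=float)
        if spec.timepoints is not None
        else np.arange(-100.0, 1001.0, 1.0)
    )
    lo, hi = spec.effect_window_ms
    if lo < t[0] or hi > t[-1]:
        raise ValueError("effect window must lie within the timepoint range")
    in_window = (t >= lo) & (t <= hi)

    rng = np.random.default_rng(spec.seed)
    patterns = rng.standard_normal((spec.n_conditions, spec.n_channels)) * spec.effect_size
    data = rng.normal(
        0.0,
        spec.noise_sd,
        size=(spec.n_conditions, spec.trials_per_condition, spec.n_channels, t.size),
    )
    data[:, :, :, in_window] += patterns[:, None, :, None]

    conditions = [f"cond{i:03d}" for i in range(spec.n_conditions)]
    return EpochSet(conditions=conditions, timepoints=t, data=data)


def gen_voxel_volume(
    spec: SimSpec,
    roi_region: np.ndarray,
    model_rdm: np.ndarray,
    mask: np.ndarray | None = None,
    activation_offset: float = 5.0,
) -> VolumeResponses:
    """Plant a model RDM's geometry into a region of a 3-D volume.

    Within ``roi_region`` the condition response vectors are an isometric
    embedding of ``model_rdm`` (classical-MDS coordinates rotated into voxel
    space by an orthonormal map) plus Gaussian noise; elsewhere responses are
    pure noise.  The embedding is exact for Euclidean-embeddable models
    (e.g. any RDM computed from response patterns); for non-embeddable
    dissimilarities the closest Euclidean geometry is planted (negative
    Gram eigenvalues discarded).  A constant ``activation_offset`` is added to ROI voxels so
    the activation map (mean response across conditions) is elevated inside
    the region without altering between-condition distances.
    """
    n_vox = int(np.prod(spec.grid_shape))
    mask = np.ones(n_vox, dtype=bool) if mask is None else np.asarray(mask, dtype=bool).ravel()
    roi = np.asarray(roi_region, dtype=bool).ravel()
    if roi.size != n_vox or mask.size != n_vox:
        raise ValueError("roi_region and mask must match grid_shape")
    if np.any(roi & ~mask):
        raise ValueError("roi_region must be a subset of the mask")

    model = np.asarray(model_rdm, dtype=float)
    n_cond = spec.n_conditions
    if model.shape != (n_cond, n_cond):
        raise ValueError(
            f"model_rdm size {model.shape} does not match condition count {n_cond}"
        )
    n_roi = int(roi.sum())

    rng = np.random.default_rng(spec.seed)
    responses = np.zeros((n_vox, n_cond))
    responses[mask] = rng.normal(0.0, spec.noise_sd, size=(int(mask.sum()), n_cond))
    if n_roi > 0:
        # classical MDS: coordinates whose distances reproduce model_rdm
        d2 = model**2
        j = np.eye(n_cond) - np.ones((n_cond, n_cond)) / n_cond
        gram = -0.5 * j @ d2 @ j
        eigvals, eigvecs = np.linalg.eigh(gram)
        keep = eigvals > 1e-10 * max(eigvals.max(), 1.0)
        coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])  # (n_cond, d)
        d = coords.shape[1]
        if n_roi < d:
            raise ValueError(
                f"roi_region has {n_roi} voxels; needs >= {d} to embed the geometry"
            )
        # random orthonormal columns: distance-preserving rotation into voxel
        # space, scaled by sqrt(n_roi) so the per-voxel signal amplitude does
        # not shrink with region size (condition distances across the full
        # region then equal sqrt(n_roi) * model_rdm)
        q, _ = np.linalg.qr(rng.standard_normal((n_roi, d)))
        responses[roi] += np.sqrt(n_roi) * (q @ coords.T) + activation_offset

    activation = np.zeros(n_vox)
    activation[mask] = responses[mask].mean(axis=1)
    return VolumeResponses(
        grid_shape=tuple(spec.grid_shape),
        mask=mask,
        responses=responses,
        activation_map=activation,
    )
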