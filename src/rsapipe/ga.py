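"""Genetic-algorithm stimulus-subset selection.

Selects a fixed-size subset of candidate stimuli whose participant-mean
ratings are maximally decorrelated across dimensions: fitness is the maximum
absolute pairwise Pearson correlation between dimension ratings within the
subset (lower is better), plus an additive penalty per violated constraint
(more than ``max_per_category`` stimuli from one category, or a required tag
such as "human face" missing from the subset).

The GA evolves fixed-size subset chromosomes with tournament selection,
subset-preserving uniform crossover, swap mutation (replace a member with a
non-member), and elitism.  A random-selection baseline (repeated uniform
draws without optimization) quantifies how much the optimization buys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synth import RatingCatalog

__all__ = [
    "GAConfig",
    "GridCell",
    "GAResult",
    "enumerate_grid",
    "assign_cell",
    "fitness",
    "run_ga",
    "random_baseline",
]


@dataclass
class GAConfig:
    """Hyperparameters for subset selection.

    Defaults mirror the study where stated (subset of 128, 10,000
    generations, at most 2 per category, required human face/body, 10,000
    random baseline draws); population/tournament/mutation/elitism settings
    are exposed knobs.
    """

    subset_size: int = 128
    n_generations: int = 10_000
    population_size: int = 200
    tournament_size: int = 3
    mutation_rate: float = 0.02
    elitism_count: int = 2
    max_per_category: int = 2
    required_tags: tuple[str, ...] = ("human face", "human body")
    penalty_weight: float = 10.0
    n_random_baseline: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be a probability")
        if self.penalty_weight < 0:
            raise ValueError("penalty_weight must be nonnegative")


@dataclass(frozen=True)
class GridCell:
    """One binary combination of the rated dimensions."""

    bits: tuple[int, ...]

    @property
    def label(self) -> str:
        return "".join(str(b) for b in self.bits)


@dataclass
class GAResult:
    best_subset: list[str]
    best_fitness: float
    fitness_trace: np.ndarray
    baseline_fitnesses: np.ndarray | None
    covered_cells: int
    corr_matrix: np.ndarray
    best_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def enumerate_grid(n_dims: int) -> list[GridCell]:
    """All 2^n_dims binary dimension combinations in binary-counting order."""
    if n_dims <= 0:
        raise ValueError("n_dims must be >= 1")
    cells = []
    for i in range(2**n_dims):
        bits = tuple((i >> (n_dims - 1 - d)) & 1 for d in range(n_dims))
        cells.append(GridCell(bits=bits))
    return cells


def assign_cell(mean_ratings: np.ndarray) -> GridCell:
    """Map mean ratings to a grid cell: bit i = 1 iff rating_i > 0."""
    mean_ratings = np.asarray(mean_ratings, dtype=float)
    if mean_ratings.ndim != 1 or mean_ratings.size == 0:
        raise ValueError("need one mean rating per dimension")
    if np.any(np.isnan(mean_ratings)):
        raise ValueError("missing dimension rating")
    return GridCell(bits=tuple(int(r > 0) for r in mean_ratings))


def _max_abs_corr(sub_means: np.ndarray) -> float:
    """Max |Pearson r| over dimension pairs; constant dims contribute 0."""
    stds = sub_means.std(axis=0)
    constant = stds == 0
    if constant.any():
        warnings.warn(
            "constant dimension within subset: its correlations treated as 0",
            stacklevel=3,
        )
        if constant.sum() >= sub_means.shape[1] - 1:
            return 0.0
        sub_means = sub_means[:, ~constant]
    corr = np.corrcoef(sub_means, rowvar=False)
    off = np.abs(corr[np.triu_indices(corr.shape[0], k=1)])
    return float(off.max()) if off.size else 0.0


def _count_violations(subset_idx: np.ndarray, categories: np.ndarray, config: GAConfig) -> int:
    cats, counts = np.unique(categories[subset_idx], return_counts=True)
    violations = int(np.sum(counts > config.max_per_category))
    present = set(cats)
    violations += sum(1 for tag in config.required_tags if tag not in present)
    return violations


def fitness(
    subset, catalog: RatingCatalog, config: GAConfig, mean_ratings: np.ndarray | None = None
) -> float:
    """Max |r| between dimensions on the subset + penalty_weight per violation.

    ``subset`` may be stimulus ids or integer indices into the catalog.
    Ratings are averaged across participants before correlating.
    """
    idx = _as_indices(subset, catalog)
    means = mean_ratings if mean_ratings is not None else catalog.mean_ratings()
    base = _max_abs_corr(means[idx])
    violations = _count_violations(idx, np.asarray(catalog.category_labels), config)
    return base + config.penalty_weight * violations


def _as_indices(subset, catalog: RatingCatalog) -> np.ndarray:
    subset = list(subset)
    if subset and isinstance(subset[0], str):
        lookup = {s: i for i, s in enumerate(catalog.stimulus_ids)}
        return np.array([lookup[s] for s in subset], dtype=int)
    return np.asarray(subset, dtype=int)


def _max_abs_corr_batch(sub_means: np.ndarray) -> np.ndarray:
    """Max |Pearson r| per member of a (batch, subset, dims) stack.

    Constant dimensions contribute 0 to the maximum (their correlations are
    undefined); matches :func:`_max_abs_corr` without its warning so batch
    evaluation of random populations stays quiet.
    """
    centered = sub_means - sub_means.mean(axis=1, keepdims=True)
    cov = np.einsum("bsi,bsj->bij", centered, centered)
    sd = np.sqrt(np.einsum("bii->bi", cov))
    denom = sd[:, :, None] * sd[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.abs(cov / denom)
    iu = np.triu_indices(sub_means.shape[2], k=1)
    off = np.nan_to_num(corr[:, iu[0], iu[1]], nan=0.0)
    return off.max(axis=1) if off.size else np.zeros(sub_means.shape[0])


class _FitnessCache:
    """Memoises subset fitness within one run; subsets recur heavily."""

    def __init__(self, means: np.ndarray, categories: np.ndarray, config: GAConfig):
        self.means = means
        self.config = config
        cats, self.codes = np.unique(categories, return_inverse=True)
        self.n_cats = cats.size
        self.required_codes = np.array(
            [np.searchsorted(cats, t) for t in config.required_tags], dtype=int
        )
        self.check_constraints = bool(
            config.penalty_weight > 0 and (config.required_tags or config.max_per_category)
        )
        self._cache: dict[bytes, float] = {}

    def _violations(self, idx: np.ndarray) -> int:
        counts = np.bincount(self.codes[idx], minlength=self.n_cats)
        v = int(np.sum(counts > self.config.max_per_category))
        v += int(np.sum(counts[self.required_codes] == 0))
        return v

    def __call__(self, idx: np.ndarray) -> float:
        return self.evaluate_population([idx])[0]

    def evaluate_population(self, population: list[np.ndarray]) -> np.ndarray:
        keys = [np.sort(ind).astype(np.int32).tobytes() for ind in population]
        fits = np.empty(len(population))
        todo = []
        for i, key in enumerate(keys):
            val = self._cache.get(key)
            if val is None:
                todo.append(i)
            else:
                fits[i] = val
        if todo:
            stack = self.means[np.stack([population[i] for i in todo])]
            base = _max_abs_corr_batch(stack)
            for j, i in zip(range(len(todo)), todo):
                val = float(base[j])
                if self.check_constraints:
                    val += self.config.penalty_weight * self._violations(population[i])
                self._cache[keys[i]] = fits[i] = val
        return fits


def _crossover(a: np.ndarray, b: np.ndarray, n_pool: int, scratch: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Subset-preserving uniform crossover: keep the intersection, fill the
    rest by sampling from the symmetric difference."""
    scratch[:] = 0
    scratch[a] += 1
    scratch[b] += 1
    common = np.where(scratch == 2)[0]
    need = a.size - common.size
    if need == 0:
        return common
    pool = np.where(scratch == 1)[0]
    chosen = rng.choice(pool, size=need, replace=False)
    return np.concatenate([common, chosen])


def _mutate(individual: np.ndarray, n_pool: int, rate: float, scratch: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Swap mutation: each gene replaced with a non-member w.p. ``rate``."""
    flips = np.where(rng.random(individual.size) < rate)[0]
    if flips.size == 0:
        return individual
    scratch[:] = 0
    scratch[individual] = 1
    outside = np.where(scratch == 0)[0]
    if outside.size == 0:
        return individual
    replacements = rng.choice(outside, size=min(flips.size, outside.size), replace=False)
    out = individual.copy()
    out[flips[: replacements.size]] = replacements
    return out


def run_ga(catalog: RatingCatalog, config: GAConfig) -> GAResult:
    """Evolve a stimulus subset minimizing the fitness; deterministic per seed."""
    n_pool = catalog.n_stimuli
    if config.subset_size > n_pool:
        raise ValueError("subset_size exceeds candidate pool")
    present = set(catalog.category_labels)
    missing = [t for t in config.required_tags if t not in present]
    if missing:
        raise ValueError(f"required tags absent from candidate pool: {missing}")

    rng = np.random.default_rng(config.seed)
    means = catalog.mean_ratings()
    categories = np.asarray(catalog.category_labels)
    evaluate = _FitnessCache(means, categories, config)

    pop = [
        rng.choice(n_pool, size=config.subset_size, replace=False)
        for _ in range(config.population_size)
    ]
    fits = evaluate.evaluate_population(pop)

    best_i = int(np.argmin(fits))
    best_ind, best_fit = pop[best_i].copy(), float(fits[best_i])
    trace = np.empty(config.n_generations + 1)
    trace[0] = best_fit
    scratch = np.zeros(n_pool, dtype=np.int8)

    for gen in range(config.n_generations):
        order = np.argsort(fits, kind="stable")
        new_pop = [pop[i].copy() for i in order[: config.elitism_count]]
        while len(new_pop) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population_size, size=config.tournament_size)
                parents.append(pop[contenders[np.argmin(fits[contenders])]])
            child = _crossover(parents[0], parents[1], n_pool, scratch, rng)
            child = _mutate(child, n_pool, config.mutation_rate, scratch, rng)
            new_pop.append(child)
        pop = new_pop
        fits = evaluate.evaluate_population(pop)
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_ind = pop[gen_best].copy()
        trace[gen + 1] = best_fit

    best_ind = np.sort(best_ind)
    sub_means = means[best_ind]
    corr = np.corrcoef(sub_means, rowvar=False) if sub_means.std(axis=0).min() > 0 else np.full(
        (means.shape[1], means.shape[1]), np.nan
    )
    cells = {assign_cell(sub_means[i]) for i in range(best_ind.size)}
    return GAResult(
        best_subset=[catalog.stimulus_ids[i] for i in best_ind],
        best_fitness=best_fit,
        fitness_trace=trace,
        baseline_fitnesses=None,
        covered_cells=len(cells),
        corr_matrix=corr,
        best_indices=best_ind,
    )


def random_baseline(catalog: RatingCatalog, config: GAConfig) -> np.ndarray:
    """Base fitness (max |r|, no penalties) of repeated uniform random draws."""
    if config.n_random_baseline < 1:
        raise ValueError("n_random_baseline must be >= 1")
    if config.subset_size > catalog.n_stimuli:
        raise ValueError("subset_size exceeds candidate pool")
    rng = np.random.default_rng(config.seed)
    means = catalog.mean_ratings()
    out = np.empty(config.n_random_baseline)
    for i in range(config.n_random_baseline):
        idx = np.sort(rng.choice(catalog.n_stimuli, size=config.subset_size, replace=False))
        out[i] = _max_abs_corr(means[idx])
    return out
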