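import numpy as np
import pytest
from hypothesis import settings

from rsapipe import RatingCatalog, SimSpec, gen_rating_catalog

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_catalog() -> RatingCatalog:
    """50-stimulus catalog with independent dimensions, 5 raters."""
    return gen_rating_catalog(SimSpec(seed=11, n_stimuli=50, n_participants=5, n_categories=10))


@pytest.fixture()
def manual_catalog() -> RatingCatalog:
    """Tiny hand-built catalog for exact fitness arithmetic."""
    ratings = np.array([
        # stimuli x dims for one participant
        [1.0, 1.0],
        [1.0, -1.0],
        [-1.0, 1.0],
        [-1.0, -1.0],
        [2.0, 2.0],
        [3.0, 3.0],
    ])[None, :, :]
    return RatingCatalog(
        stimulus_ids=[f"s{i}" for i in range(6)],
        category_labels=["human face", "human body", "c1", "c2", "c3", "c3"],
        dimension_names=["d0", "d1"],
        ratings=ratings,
    )


def random_rdm(rng: np.random.Generator, n: int) -> np.ndarray:
    """Valid random RDM values (symmetric, zero diagonal, nonnegative)."""
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = rng.uniform(0.1, 2.0, size=iu[0].size)
    return m + m.T
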