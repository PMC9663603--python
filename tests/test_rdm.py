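"""RDM construction, comparison, noise ceilings, consistency summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsapipe import (
    RDM,
    RatingCatalog,
    between_participant_consistency,
    compare_spearman,
    gen_rating_catalog,
    gen_subject_rdm_stack,
    model_rdm_from_dimension,
    noise_ceiling,
    rdm_from_patterns,
    vectorize,
    within_participant_consistency,
)
from rsapipe import SimSpec, SubjectRDMStack

from conftest import random_rdm


class TestRDMConstruction:
    def test_identical_rows_zero_distance(self):
        rdm = rdm_from_patterns(np.ones((3, 4)))
        np.testing.assert_allclose(rdm.values, 0)

    @pytest.mark.parametrize(
        "patterns,expected",
        [
            ([[3.0], [7.0]], 4.0),
            ([[0.0, 0.0], [3.0, 4.0]], 5.0),
        ],
    )
    def test_euclidean_examples(self, patterns, expected):
        assert rdm_from_patterns(np.array(patterns)).values[0, 1] == pytest.approx(expected)

    def test_missing_values_rejected_naming_stimulus(self):
        patterns = np.array([[1.0, 2.0], [np.nan, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="s1"):
            rdm_from_patterns(patterns, stimulus_ids=["s0", "s1", "s2"])

    def test_euclidean_rdm_triangle_inequality(self):
        rng = np.random.default_rng(0)
        rdm = rdm_from_patterns(rng.standard_normal((10, 6)))
        v = rdm.values
        for i, j, k in rng.integers(0, 10, size=(50, 3)):
            assert v[i, j] <= v[i, k] + v[k, j] + 1e-12


class TestDimensionModel:
    def _catalog(self, means):
        ratings = np.asarray(means, dtype=float)[None, :, None]
        return RatingCatalog([f"s{i}" for i in range(len(means))],
                             ["c"] * len(means), ["dim"], ratings)

    def test_scale_extremes(self):
        rdm = model_rdm_from_dimension(self._catalog([10.0, -10.0]), "dim")
        assert rdm.values[0, 1] == pytest.approx(20.0)

    def test_equal_ratings_zero_rdm(self):
        rdm = model_rdm_from_dimension(self._catalog([2.0, 2.0, 2.0]), "dim")
        np.testing.assert_allclose(rdm.values, 0)

    def test_absolute_difference_oracle(self):
        rdm = model_rdm_from_dimension(self._catalog([0.0, 5.0, -5.0]), "dim")
        np.testing.assert_allclose(vectorize(rdm), [5.0, 5.0, 10.0])

    def test_unknown_dimension_rejected(self):
        with pytest.raises(ValueError, match="unknown dimension"):
            model_rdm_from_dimension(self._catalog([1.0, 2.0]), "nope")


class TestVectorize:
    @pytest.mark.parametrize("n", [2, 3, 7, 128])
    def test_length_is_n_choose_2(self, n):
        rng = np.random.default_rng(n)
        assert vectorize(random_rdm(rng, n)).size == n * (n - 1) // 2

    def test_row_major_ordering(self):
        m = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        np.testing.assert_allclose(vectorize(m), [1.0, 2.0, 3.0])

    def test_asymmetric_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            vectorize(m)


class TestSpearman:
    def _rdm(self, values, ids=None):
        ids = ids or [f"s{i}" for i in range(values.shape[0])]
        return RDM(ids, values)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        rdm = self._rdm(random_rdm(rng, 6))
        assert compare_spearman(rdm, rdm) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        rng = np.random.default_rng(2)
        a = random_rdm(rng, 5)
        v = vectorize(a)
        # build a matrix whose vector ranks are exactly reversed
        order = np.argsort(np.argsort(v))
        reversed_vals = np.sort(v)[::-1][order]
        b = np.zeros_like(a)
        iu = np.triu_indices(5, k=1)
        b[iu] = reversed_vals
        b += b.T
        assert compare_spearman(self._rdm(a), self._rdm(b)) == pytest.approx(-1.0)

    def test_textbook_rho(self):
        # untied vectors (1..6) vs (1,3,2,4,5,6): sum d^2 = 2, so
        # rho = 1 - 6*2/(6*(36-1)) = 0.9428571...
        iu4 = np.triu_indices(4, k=1)
        a = np.zeros((4, 4))
        a[iu4] = [1, 2, 3, 4, 5, 6]
        a += a.T
        b = np.zeros((4, 4))
        b[iu4] = [1, 3, 2, 4, 5, 6]
        b += b.T
        ids = list("wxyz")
        rho = compare_spearman(RDM(ids, a), RDM(ids, b))
        assert rho == pytest.approx(1 - 6 * 2 / (6 * 35))

    def test_constant_rdm_undefined_with_warning(self):
        ids = ["a", "b", "c"]
        const = RDM(ids, np.ones((3, 3)) - np.eye(3))
        rng = np.random.default_rng(3)
        other = RDM(ids, random_rdm(rng, 3))
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(compare_spearman(const, other))

    @given(seed=st.integers(0, 2**20), power=st.floats(0.3, 3.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_monotone_transforms(self, seed, power):
        rng = np.random.default_rng(seed)
        a, b = random_rdm(rng, 6), random_rdm(rng, 6)
        ids = [f"s{i}" for i in range(6)]
        base = compare_spearman(RDM(ids, a), RDM(ids, b))
        transformed = compare_spearman(RDM(ids, a**power), RDM(ids, b))
        assert transformed == pytest.approx(base, abs=1e-12)


class TestNoiseCeiling:
    def test_identical_subjects_ceiling_is_one(self):
        rng = np.random.default_rng(4)
        m = random_rdm(rng, 8)
        stack = gen_subject_rdm_stack([m], [1.0], 0.0, 5, seed=0)
        lower, upper = noise_ceiling(stack)
        assert lower == pytest.approx(1.0)
        assert upper == pytest.approx(1.0)

    @given(seed=st.integers(0, 2**20))
    @settings(max_examples=15, deadline=None)
    def test_lower_never_exceeds_upper(self, seed):
        rng = np.random.default_rng(seed)
        rdms = np.stack([random_rdm(rng, 6) for _ in range(4)])
        stack = SubjectRDMStack([f"s{i}" for i in range(4)],
                                [f"x{i}" for i in range(6)], rdms)
        lower, upper = noise_ceiling(stack)
        assert lower <= upper + 1e-12

    def test_independent_subjects_ceiling_matches_null_expectation(self):
        # with N independent subjects the leave-one-out bound is ~0 while the
        # include-self bound concentrates near 1/sqrt(N) (self-correlation of
        # one subject with a mean containing it)
        rng = np.random.default_rng(5)
        n_subj = 20
        rdms = np.stack([random_rdm(rng, 16) for _ in range(n_subj)])
        stack = SubjectRDMStack([f"s{i}" for i in range(n_subj)],
                                [f"x{i}" for i in range(16)], rdms)
        lower, upper = noise_ceiling(stack)
        assert abs(lower) < 0.15
        assert upper == pytest.approx(1 / np.sqrt(n_subj), abs=0.15)

    def test_single_subject_rejected(self):
        rng = np.random.default_rng(6)
        stack = SubjectRDMStack(["s0"], [f"x{i}" for i in range(5)],
                                random_rdm(rng, 5)[None])
        with pytest.raises(ValueError):
            noise_ceiling(stack)


class TestConsistency:
    def _catalog(self, ratings, repeats=None, repeat_ids=None):
        n_stim = ratings.shape[1]
        return RatingCatalog([f"s{i}" for i in range(n_stim)], ["c"] * n_stim,
                             [f"d{i}" for i in range(ratings.shape[2])], ratings,
                             repeat_ids=repeat_ids or [],
                             repeat_ratings=repeats)

    def test_identical_participants_give_one(self):
        base = np.random.default_rng(7).uniform(-10, 10, size=(1, 10, 2))
        cat = self._catalog(np.repeat(base, 3, axis=0))
        assert between_participant_consistency(cat) == pytest.approx(1.0)

    def test_opposite_participants_give_minus_one(self):
        base = np.random.default_rng(8).uniform(-5, 5, size=(10, 2))
        cat = self._catalog(np.stack([base, -base]))
        assert between_participant_consistency(cat) == pytest.approx(-1.0)

    def test_independent_participants_near_zero(self):
        rng = np.random.default_rng(9)
        cat = self._catalog(rng.uniform(-10, 10, size=(6, 500, 5)))
        assert abs(between_participant_consistency(cat)) < 0.1

    def test_identical_repeats_give_one(self):
        rng = np.random.default_rng(10)
        ratings = rng.uniform(-10, 10, size=(2, 8, 2))
        cat = self._catalog(ratings, repeats=ratings[:, :3, :],
                            repeat_ids=["s0", "s1", "s2"])
        assert within_participant_consistency(cat) == pytest.approx(1.0)

    def test_consistency_decreases_with_noise(self):
        vals = []
        for noise in (0.5, 2.0, 6.0):
            cat = gen_rating_catalog(SimSpec(seed=42, n_stimuli=100, n_participants=6,
                                             noise_sd=noise, stable_bias_sd=0.0))
            vals.append(within_participant_consistency(cat))
        assert vals[0] > vals[1] > vals[2]

    def test_single_repeat_rejected(self):
        rng = np.random.default_rng(11)
        ratings = rng.uniform(-10, 10, size=(2, 8, 2))
        cat = self._catalog(ratings, repeats=ratings[:, :1, :], repeat_ids=["s0"])
        with pytest.raises(ValueError, match="at least 2"):
            within_participant_consistency(cat)
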