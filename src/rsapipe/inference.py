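"""Nonparametric group inference: Wilcoxon signed-rank, BH-FDR, latencies.

Participants are treated as random effects throughout: model fits, decoding
accuracies and searchlight correlations are tested against their null value
with the one-sided Wilcoxon signed-rank test (exact sign-enumeration null for
small samples without tied absolute ranks, normal approximation with
continuity correction otherwise), and multiple comparisons within each
family (timepoints of a time course, model pairs of a comparison panel,
voxels of a map) are handled by Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import wilcoxon as _scipy_wilcoxon
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "SignificanceTimecourse",
    "wilcoxon_signed_rank",
    "fdr_bh",
    "pairwise_model_comparison",
    "timecourse_significance",
]

#: Largest sample for which the exact sign-enumeration null is used.
EXACT_N_MAX = 25


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_effective: int
    alternative: str

    @property
    def defined(self) -> bool:
        return not np.isnan(self.p_value)


@dataclass
class SignificanceTimecourse:
    timepoints: np.ndarray
    p_values: np.ndarray
    rejected: np.ndarray
    onset_ms: float | None
    peak_ms: float
    group_mean: np.ndarray


def wilcoxon_signed_rank(values, null_value: float = 0.0, alternative: str = "greater") -> TestResult:
    """Wilcoxon signed-rank test of ``values`` against ``null_value``.

    Zero differences are discarded (classical treatment).  The exact null
    (over all sign assignments of the observed absolute ranks) is used when
    the effective sample is at most 25 — via the standard distribution for
    untied ranks, or a direct convolution over the observed (possibly tied,
    average) ranks otherwise; larger samples use the normal approximation
    with continuity correction.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    diffs = np.asarray(values, dtype=float) - null_value
    diffs = diffs[diffs != 0]
    n_eff = diffs.size
    if n_eff == 0:
        logger.warning("all differences zero: Wilcoxon statistic undefined")
        return TestResult(np.nan, np.nan, 0, alternative)
    has_ties = np.unique(np.abs(diffs)).size < n_eff
    if n_eff <= EXACT_N_MAX and has_ties:
        return _exact_tied(diffs, alternative)
    method = "exact" if n_eff <= EXACT_N_MAX else "approx"
    res = _scipy_wilcoxon(
        diffs,
        alternative=alternative,
        method=method,
        correction=(method == "approx"),
        zero_method="wilcox",
    )
    return TestResult(float(res.statistic), float(res.pvalue), int(n_eff), alternative)


def _exact_tied(diffs: np.ndarray, alternative: str) -> TestResult:
    """Exact signed-rank p conditional on the observed tied (average) ranks.

    Convolves the sign-flip distribution of W+ over doubled ranks (doubling
    makes half-integer average ranks integral); cost O(n * n^2) counts.
    """
    from scipy.stats import rankdata

    ranks2 = np.round(2 * rankdata(np.abs(diffs))).astype(int)
    w_obs2 = int(ranks2[diffs > 0].sum())
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    counts /= counts.sum()
    p_ge = counts[w_obs2:].sum()
    if alternative == "greater":
        p = p_ge
    else:
        p_le = counts[: w_obs2 + 1].sum()
        p = min(1.0, 2 * min(p_ge, p_le))
    return TestResult(w_obs2 / 2.0, float(p), int(diffs.size), alternative)


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values).

    Undefined (NaN) p-values are never rejected and are excluded from the
    family size m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if not 0 < q < 1:
        raise ValueError("q must be in (0,1)")
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0,1]")
    rejected = np.zeros(p.shape, dtype=bool)
    adjusted = np.full(p.shape, np.nan)
    if finite.any():
        rej, adj, _, _ = multipletests(p[finite], alpha=q, method="fdr_bh")
        rejected[finite] = rej
        adjusted[finite] = adj
    return rejected, adjusted


def pairwise_model_comparison(
    per_subject_scores: np.ndarray,
    model_names: list[str] | None = None,
    q: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Wilcoxon on per-subject score differences for every model pair.

    Returns a symmetric (n_models, n_models) p-value matrix (NaN diagonal and
    NaN where all differences are zero) and the BH-FDR rejection mask applied
    jointly across all pairs.
    """
    scores = np.asarray(per_subject_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need subjects x models with >=2 of each")
    n_models = scores.shape[1]
    names = model_names or [f"model{m}" for m in range(n_models)]
    logger.info("pairwise model comparison: FDR family = all %d pairs of %s",
                n_models * (n_models - 1) // 2, names)
    pairs = list(combinations(range(n_models), 2))
    p_flat = np.array([
        wilcoxon_signed_rank(scores[:, i] - scores[:, j], 0.0, "two-sided").p_value
        for i, j in pairs
    ])
    rej_flat, _ = fdr_bh(p_flat, q)
    p_mat = np.full((n_models, n_models), np.nan)
    rej_mat = np.zeros((n_models, n_models), dtype=bool)
    for (i, j), p, r in zip(pairs, p_flat, rej_flat):
        p_mat[i, j] = p_mat[j, i] = p
        rej_mat[i, j] = rej_mat[j, i] = r
    return p_mat, rej_mat


def timecourse_significance(
    per_subject_stat: np.ndarray,
    timepoints,
    null_value: float = 0.0,
    q: float = 0.05,
) -> SignificanceTimecourse:
    """Per-timepoint one-sided Wilcoxon vs ``null_value`` with FDR across time.

    Onset is the earliest FDR-rejected timepoint (absent if none); the peak
    is the timepoint of the maximum group-mean statistic, earliest on ties.
    """
    stat = np.asarray(per_subject_stat, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if stat.ndim != 2 or stat.shape[0] < 2:
        raise ValueError("need subjects x timepoints with >=2 subjects")
    if stat.shape[1] != t.size:
        raise ValueError("timepoint count mismatch")
    logger.info("timecourse significance: FDR family = %d timepoints", t.size)
    p = np.array([
        wilcoxon_signed_rank(stat[:, i], null_value, "greater").p_value
        for i in range(t.size)
    ])
    rejected, _ = fdr_bh(p, q)
    onset = float(t[rejected][0]) if rejected.any() else None
    group_mean = stat.mean(axis=0)
    peak = float(t[int(np.argmax(group_mean))])
    return SignificanceTimecourse(
        timepoints=t,
        p_values=p,
        rejected=rejected,
        onset_ms=onset,
        peak_ms=peak,
        group_mean=group_mean,
    )
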