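"""Two-class unpaired SAM with permutation-estimated FDR.

The per-gene statistic is the moderated t-like ratio

    d = (mean_case - mean_control) / (s + s0)

with ``s`` the Tusher pooled standard error

    s = sqrt( ((1/n1 + 1/n2) / (n1 + n2 - 2)) * (SS1 + SS2) )

and ``s0`` a small "fudge factor" that stabilises genes with tiny
variance.  Significance is assessed by permuting the group labels: for a
grid of symmetric |d| thresholds, the false discovery rate is the median
number of permuted statistics exceeding the threshold divided by the
observed number.  A gene's q-value is the smallest such FDR at which the
gene would be called.

When the number of distinct label assignments C(n, n_case) is smaller
than the requested permutation count, all assignments are enumerated
instead of sampled, making small designs exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SAMConfig",
    "DEGeneSet",
    "sam_statistic",
    "estimate_s0",
    "permutation_fdr",
    "call_de_genes",
]

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class SAMConfig:
    """Settings for one SAM contrast.

    s0_method is either ``"tusher_cv_minimization"`` (scan s0 candidates at
    the 0,5,...,100 percentiles of s and minimise the coefficient of
    variation of median |d| across s-quantile windows) or
    ``"fixed_percentile"`` (s0 = ``s0_percentile``-quantile of s; fast and
    adequate for simulations).
    """

    seed: int
    n_permutations: int = 10_000
    target_fdr: float = 0.01
    s0_method: str = "tusher_cv_minimization"
    s0_percentile: float = 0.5

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.target_fdr < 1:
            raise ValueError("target_fdr must be in (0, 1)")
        if self.s0_method not in ("tusher_cv_minimization", "fixed_percentile"):
            raise ValueError(f"unknown s0_method: {self.s0_method!r}")


@dataclass
class DEGeneSet:
    """Called DE genes of one contrast with their dysregulation direction."""

    contrast: str
    directions: dict[str, str]

    @property
    def genes(self) -> set[str]:
        return set(self.directions)

    def __len__(self) -> int:
        return len(self.directions)


def _pooled_parts(a: np.ndarray, b: np.ndarray):
    """Mean difference and pooled standard error per gene (rows)."""
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss_a = ((a - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((b - mean_b[:, None]) ** 2).sum(axis=1)
    coef = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    s = np.sqrt(coef * (ss_a + ss_b))
    return mean_a - mean_b, s


def sam_statistic(
    group_a_values: np.ndarray, group_b_values: np.ndarray, s0: float
):
    """Per-gene SAM statistic d and pooled standard error s.

    Rows are genes, columns samples.  Returns ``(d, s, delta_mean)`` with
    ``delta_mean = mean_A - mean_B``.  With zero variance in both groups
    and s0 = 0, d is ±inf with the sign of the mean difference (0 when the
    means also coincide); such genes are flagged in the log.
    """
    a = np.atleast_2d(np.asarray(group_a_values, dtype=float))
    b = np.atleast_2d(np.asarray(group_b_values, dtype=float))
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    delta, s = _pooled_parts(a, b)
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, delta / np.where(denom > 0, denom, 1.0),
                     np.sign(delta) * np.inf)
    d = np.where((denom == 0) & (delta == 0), 0.0, d)
    n_degenerate = int(((denom == 0)).sum())
    if n_degenerate:
        logger.warning("sam_statistic: %d genes with zero variance and s0=0",
                       n_degenerate)
    return d, s, delta


def estimate_s0(
    d_numerators: np.ndarray,
    s_values: np.ndarray,
    method: str = "tusher_cv_minimization",
    percentile: float = 0.5,
    n_windows: int = 10,
) -> float:
    """Estimate the fudge factor s0 from per-gene numerators and scales.

    ``tusher_cv_minimization``: candidates are the 0,5,...,100 percentiles
    of s; for each candidate the genes are binned into ``n_windows``
    s-quantile windows and the candidate minimising the coefficient of
    variation of the per-window median |d| is chosen (ties go to the
    smallest candidate).  ``fixed_percentile``: simply the given quantile
    of s.
    """
    r = np.asarray(d_numerators, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if r.shape != s.shape or r.ndim != 1:
        raise ValueError("d_numerators and s_values must be 1-D and equal length")
    if s.size < 10:
        raise ValueError("need >= 10 genes to estimate s0")
    if np.allclose(s, s[0]):
        logger.info("estimate_s0: all s identical; returning that value")
        return float(s[0])
    if method == "fixed_percentile":
        return float(np.percentile(s, 100.0 * percentile))
    if method != "tusher_cv_minimization":
        raise ValueError(f"unknown s0 method: {method!r}")

    candidates = np.percentile(s, np.arange(0, 101, 5))
    edges = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
    best_alpha, best_cv = float(candidates[0]), math.inf
    for alpha in candidates:
        absd = np.abs(r / (s + alpha))
        med = np.array([
            np.median(absd[window == w])
            for w in range(n_windows)
            if (window == w).any()
        ])
        mean = med.mean()
        cv = med.std() / mean if mean > 0 else math.inf
        if cv < best_cv - 1e-12:
            best_cv, best_alpha = cv, float(alpha)
    return best_alpha


def _permutation_masks(n: int, n_a: int, n_perm: int, seed: int) -> np.ndarray:
    """Boolean (B × n) masks of group-A membership.

    Enumerates all C(n, n_a) assignments when fewer than ``n_perm``,
    otherwise samples ``n_perm`` uniformly at random with the given seed.
    """
    total = math.comb(n, n_a)
    if total < n_perm:
        masks = np.zeros((total, n), dtype=bool)
        for b, idx in enumerate(combinations(range(n), n_a)):
            masks[b, list(idx)] = True
        logger.info("permutation_fdr: enumerating all %d label assignments", total)
        return masks
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=bool)
    for b in range(n_perm):
        masks[b, rng.permutation(n)[:n_a]] = True
    return masks


def permutation_fdr(
    matrix: ExpressionMatrix, group_a: str, group_b: str, config: SAMConfig
) -> pd.DataFrame:
    """SAM with permutation-estimated FDR for one two-group contrast.

    Returns a per-gene DataFrame with columns ``d``, ``s``, ``delta_mean``
    (mean(group_a) − mean(group_b)), ``direction``, ``q_value`` and
    ``called`` (q ≤ target FDR).  For a symmetric threshold grid taken at
    the observed |d| values, FDR(cut) = median over permutations of
    #{|d*| ≥ cut} divided by #{|d| ≥ cut}; q-values are the smallest FDR
    over the thresholds a gene passes, hence monotone in |d|.
    """
    va = matrix.group_values(group_a)
    vb = matrix.group_values(group_b)
    samples_a, samples_b = matrix.group_samples(group_a), matrix.group_samples(group_b)
    if set(samples_a) & set(samples_b):
        raise ValueError("groups must be disjoint")
    n_a, n_b = va.shape[1], vb.shape[1]
    genes = matrix.gene_ids

    delta, s = _pooled_parts(va, vb)
    s0 = estimate_s0(delta, s, config.s0_method, config.s0_percentile)
    d = delta / (s + s0)

    X = np.concatenate([va, vb], axis=1)  # genes × (n_a + n_b)
    n = n_a + n_b
    # center rows: group means/SS are shift-invariant, and small magnitudes
    # keep the sum2 - n*mean^2 identity below well conditioned
    X = X - X.mean(axis=1, keepdims=True)
    masks = _permutation_masks(n, n_a, config.n_permutations, config.seed)
    P = masks.astype(float).T  # n × B
    tot = X.sum(axis=1)
    tot2 = (X**2).sum(axis=1)
    sum_a = X @ P
    sum2_a = (X**2) @ P
    sum_b = tot[:, None] - sum_a
    sum2_b = tot2[:, None] - sum2_a
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    ss_a = np.maximum(sum2_a - n_a * mean_a**2, 0.0)
    ss_b = np.maximum(sum2_b - n_b * mean_b**2, 0.0)
    coef = (1.0 / n_a + 1.0 / n_b) / (n - 2)
    s_perm = np.sqrt(coef * (ss_a + ss_b))
    d_perm = (mean_a - mean_b) / (s_perm + s0)

    absd = np.abs(d)
    order = np.argsort(-absd, kind="stable")
    cuts = absd[order]  # descending grid of thresholds
    asc = np.sort(absd)
    n_obs = absd.size - np.searchsorted(asc, cuts, side="left")

    perm_abs = np.sort(np.abs(d_perm), axis=0)  # per permutation (column)
    n_perm_exceed = np.empty((perm_abs.shape[1], cuts.size))
    G = absd.size
    # relative tolerance so a permuted statistic that ties an observed
    # threshold up to fp rounding still counts as ">= cut"
    thresh = cuts * (1.0 - 1e-9)
    for b in range(perm_abs.shape[1]):
        n_perm_exceed[b] = G - np.searchsorted(perm_abs[:, b], thresh, side="left")
    med_false = np.median(n_perm_exceed, axis=0)

    fdr = med_false / np.maximum(1, n_obs)
    # smallest FDR over thresholds the gene passes (suffix minimum on the
    # descending grid), clipped to [0, 1]
    q_sorted = np.minimum.accumulate(np.minimum(fdr, 1.0)[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    direction = np.where(delta > 0, UP, np.where(delta < 0, DOWN, ""))
    result = pd.DataFrame(
        {
            "d": d,
            "s": s,
            "delta_mean": delta,
            "direction": direction,
            "q_value": q,
            "called": q <= config.target_fdr,
        },
        index=genes,
    )
    result.index.name = "gene_id"
    logger.info(
        "permutation_fdr %s vs %s: %d/%d genes called at FDR %.3g (s0=%.4g)",
        group_a, group_b, int(result["called"].sum()), len(result),
        config.target_fdr, s0,
    )
    return result


def call_de_genes(
    matrix: ExpressionMatrix, case_group: str, control_group: str, config: SAMConfig
) -> DEGeneSet:
    """Run SAM for case vs control and return the called genes with direction.

    Direction is up iff mean(case) − mean(control) > 0, down iff < 0; a
    called gene with exactly zero mean difference has no defined direction
    and is excluded with a warning.
    """
    table = permutation_fdr(matrix, case_group, control_group, config)
    called = table[table["called"]]
    zero = called[called["direction"] == ""]
    if len(zero):
        logger.warning(
            "call_de_genes: %d called genes with zero mean difference excluded",
            len(zero),
        )
    called = called[called["direction"] != ""]
    return DEGeneSet(
        contrast=f"{case_group}_vs_{control_group}",
        directions=dict(zip(called.index.astype(str), called["direction"])),
    )
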