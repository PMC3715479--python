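"""Exact tail probabilities and multiple-testing procedures.

Every enrichment-style question in this package reduces to a one-sided
"at least as extreme as observed" tail probability: hypergeometric tails
for set overlaps, binomial tails for direction concordance against a fair
coin, and Pearson chi-square for clinical contingency tables.  Tails are
summed in log space via ``logsumexp`` so that probabilities far below the
double-precision floor (common for genome-scale overlaps) remain
representable; results carry both a linear ``p_value`` (which may round to
0.0) and a finite ``log10_p``.

Adjustment for multiple testing uses the Benjamini–Yekutieli step-up
procedure, which is valid under arbitrary dependence between tests — the
appropriate choice for Gene Ontology terms, whose gene memberships are
heavily nested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, chi2_contingency
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TailTestResult",
    "hypergeom_tail",
    "binom_tail",
    "chisq_independence",
    "by_adjust",
    "fisher_exact_2x2",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class TailTestResult:
    """Outcome of a one-sided tail test.

    ``p_value`` is the linear-scale probability and may underflow to 0.0
    for extreme inputs; ``log10_p`` is always finite unless the tail is
    analytically zero.  ``parameters`` records the exact tuple tested so
    that a result can be recomputed bit-identically.
    """

    p_value: float
    log10_p: float
    parameters: tuple
    statistic: float = math.nan
    tail: str = "greater"

    def as_row(self, test_name: str) -> dict:
        """Flatten to a dict suitable for a TSV report row."""
        return {
            "test": test_name,
            "parameters": ";".join(str(v) for v in self.parameters),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "log10_p": self.log10_p,
        }


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


def _log_hypergeom_pmf(i: np.ndarray, K: int, n: int, N: int) -> np.ndarray:
    # log C(K, i) + log C(N-K, n-i) - log C(N, n)
    return (
        gammaln(K + 1)
        - gammaln(i + 1)
        - gammaln(K - i + 1)
        + gammaln(N - K + 1)
        - gammaln(n - i + 1)
        - gammaln(N - K - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_tail(k: int, K: int, n: int, N: int) -> TailTestResult:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    The urn model: ``N`` items in the universe, ``K`` of them marked, ``n``
    drawn without replacement, ``k`` marked items observed in the draw.

    Parameters are validated against the urn constraints; violations raise
    ``ValueError`` naming the violated inequality.
    """
    _require(0 <= K <= N, f"need 0 <= K <= N, got K={K}, N={N}")
    _require(0 <= n <= N, f"need 0 <= n <= N, got n={n}, N={N}")
    _require(0 <= k <= min(n, K), f"need 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")

    lower_support = max(0, n + K - N)
    if k <= lower_support:
        return TailTestResult(1.0, 0.0, (k, K, n, N))
    i = np.arange(k, min(n, K) + 1)
    log_p = float(logsumexp(_log_hypergeom_pmf(i, K, n, N)))
    log_p = min(log_p, 0.0)
    return TailTestResult(float(np.exp(log_p)), log_p / _LN10, (k, K, n, N))


def binom_tail(k: int, n: int, p: float) -> TailTestResult:
    """Upper tail P(X >= k) for X ~ Binomial(n, p), summed in log space."""
    _require(0 <= k <= n, f"need 0 <= k <= n, got k={k}, n={n}")
    _require(0.0 <= p <= 1.0, f"need 0 <= p <= 1, got p={p}")

    if k == 0:
        return TailTestResult(1.0, 0.0, (k, n, p))
    if p == 0.0:
        return TailTestResult(0.0, -math.inf, (k, n, p))
    if p == 1.0:
        return TailTestResult(1.0, 0.0, (k, n, p))
    i = np.arange(k, n + 1)
    log_pmf = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * math.log(p)
        + (n - i) * math.log1p(-p)
    )
    log_p = min(float(logsumexp(log_pmf)), 0.0)
    return TailTestResult(float(np.exp(log_p)), log_p / _LN10, (k, n, p))


def chisq_independence(table, correction: bool = False) -> TailTestResult:
    """Pearson chi-square test of independence on an r x c count table.

    Rows or columns whose total is zero are dropped before testing.  By
    default no Yates continuity correction is applied (the usual choice
    for r x c tables); pass ``correction=True`` for the corrected 2x2
    variant.
    """
    t = np.asarray(table, dtype=float)
    _require(t.ndim == 2, "contingency table must be 2-dimensional")
    _require((t >= 0).all(), "contingency table entries must be non-negative")
    t = t[t.sum(axis=1) > 0]
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError(
            "undefined test: fewer than 2 non-empty rows or columns after "
            "dropping empty margins"
        )
    stat, _, dof, _ = chi2_contingency(t, correction=correction)
    log_p = float(chi2.logsf(stat, dof))
    return TailTestResult(
        float(np.exp(log_p)), log_p / _LN10, tuple(t.shape) + (dof,), statistic=float(stat)
    )


def by_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted p-values.

    Uses the dependence correction factor c(m) = sum_{i=1..m} 1/i; the
    output is in input order and elementwise >= the input.  An empty input
    yields an empty array.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    _require(bool(((p >= 0) & (p <= 1)).all()), "p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def fisher_exact_2x2(table) -> TailTestResult:
    """Two-sided Fisher exact test for a 2x2 table (experimental).

    Built directly on hypergeometric point probabilities: the p-value sums
    the probabilities of all tables with the observed margins whose point
    probability does not exceed the observed one (with a 1+1e-7 tolerance
    factor against ties lost to rounding).  Provided for the occasional
    small-count association check; the package's main tests are the
    one-sided tails above.
    """
    t = np.asarray(table, dtype=float)
    _require(t.shape == (2, 2), "fisher_exact_2x2 requires a 2x2 table")
    _require((t >= 0).all(), "contingency table entries must be non-negative")
    a = int(t[0, 0])
    K = int(t[0, 0] + t[0, 1])  # row-1 total
    n = int(t[0, 0] + t[1, 0])  # column-1 total
    N = int(t.sum())
    lo, hi = max(0, n + K - N), min(n, K)
    i = np.arange(lo, hi + 1)
    log_pmf = _log_hypergeom_pmf(i, K, n, N)
    log_obs = log_pmf[a - lo]
    keep = log_pmf <= log_obs + math.log1p(1e-7)
    log_p = min(float(logsumexp(log_pmf[keep])), 0.0)
    return TailTestResult(
        float(np.exp(log_p)), log_p / _LN10, (a, K, n, N), tail="two-sided"
    )
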