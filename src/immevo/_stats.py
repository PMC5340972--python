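"""Shared statistical primitives: exact small-sample tests and multiplicity control.

Two-sided conventions used throughout:

* Fisher exact: sum of hypergeometric probabilities not exceeding the observed
  table's probability (the "minlike" convention, as in R's fisher.test).
* rank-sum / signed-rank: ``min(1, 2 * min(P(S <= s), P(S >= s)))`` on the
  exact null distribution of the statistic, computed by dynamic programming.

Exact paths are used for small samples without ties; larger samples fall back
to the normal approximation with tie correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_exact_test",
    "rank_sum_test",
    "signed_rank_test",
    "holm_adjust_z",
    "stouffer_combine",
]


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    exact: bool = False
    flag: str | None = None


def fisher_exact_test(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    Degenerate margins (an all-zero row or column) yield p = 1 with a flag, and
    an undefined (nan) odds ratio where a margin is empty.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("Fisher exact test requires a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        a, b, c, d = t.ravel()
        if b * c == 0 and a * d == 0:
            odds = float("nan")
        else:
            odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        return TestResult(statistic=odds, pvalue=1.0, exact=True, flag="degenerate margin")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), pvalue=float(p), exact=True)


def _mann_whitney_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Counts of rank configurations per U value (no ties), by DP recursion.

    ``f[n1, n2, u]`` counts subsets; standard recursion
    f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u).
    Returns the array of counts for u = 0 .. n1*n2.
    """
    max_u = n1 * n2
    # f[j][u] for current i
    prev = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
    for j in range(n2 + 1):
        prev[j][0] = 1.0  # i = 0
    for i in range(1, n1 + 1):
        cur = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
        cur[0][0] = 1.0
        for j in range(1, n2 + 1):
            cur[j][:] = cur[j - 1]
            cur[j][j:] += prev[j][: max_u + 1 - j]
        prev = cur
    return prev[n2]


def rank_sum_test(x, y, exact_max_n: int = 20) -> TestResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Exact null distribution (DP over U) when both samples have at most
    ``exact_max_n`` observations and there are no ties; otherwise the normal
    approximation with midranks and tie correction.
    Statistic reported is U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("rank_sum_test requires nonempty samples")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and n1 <= exact_max_n and n2 <= exact_max_n:
        counts = _mann_whitney_u_distribution(n1, n2)
        total = counts.sum()
        u = int(round(u1))
        cdf = counts[: u + 1].sum() / total
        sf = counts[u:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return TestResult(statistic=float(u1), pvalue=float(p), exact=True)
    # normal approximation with tie correction
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return TestResult(statistic=float(u1), pvalue=1.0, exact=False, flag="zero variance")
    z = (u1 - mu) / math.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(statistic=float(u1), pvalue=float(min(1.0, p)), exact=False)


def _signed_rank_distribution(ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per W+ value for the given (integer) ranks."""
    max_w = int(ranks.sum())
    f = np.zeros(max_w + 1)
    f[0] = 1.0
    for r in ranks:
        r = int(r)
        g = f.copy()
        g[r:] += f[: max_w + 1 - r]
        f = g
    return f


def signed_rank_test(x, y=None, exact_max_n: int = 15) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; if all differences are zero, p = 1.
    Exact distribution (2^n sign DP) for n <= ``exact_max_n``; tied magnitudes
    are handled exactly by doubling the midranks to integers.  Larger samples
    use the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    if d.size == 0:
        return TestResult(statistic=0.0, pvalue=1.0, exact=True, flag="all differences zero")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = ranks[d > 0].sum()
    n = d.size
    if n <= exact_max_n:
        # midranks are multiples of 1/2: doubling keeps the DP integral
        counts = _signed_rank_distribution(np.round(2 * ranks).astype(int))
        total = counts.sum()
        w = int(round(2 * w_plus))
        cdf = counts[: w + 1].sum() / total
        sf = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return TestResult(statistic=float(w_plus), pvalue=float(p), exact=True)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if sigma2 <= 0:
        return TestResult(statistic=float(w_plus), pvalue=1.0, exact=False, flag="zero variance")
    z = (w_plus - mu) / math.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(statistic=float(w_plus), pvalue=float(min(1.0, p)), exact=False)


def holm_adjust_z(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Holm step-down adjustment of two-sided p-values from z-scores.

    Returns ``(p_raw, p_adj, z_adj)`` where the adjusted z carries the sign of
    the raw z and satisfies ``|z_adj| <= |z|``.
    """
    z = np.asarray(z, dtype=float)
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    if z.size == 0:
        return p_raw, p_raw.copy(), z.copy()
    _, p_adj, _, _ = multipletests(p_raw, method="holm")
    z_adj_mag = stats.norm.isf(np.clip(p_adj, 1e-300, 1.0) / 2.0)
    z_adj_mag = np.minimum(z_adj_mag, np.abs(z))
    z_adj_mag = np.maximum(z_adj_mag, 0.0)
    return p_raw, p_adj, np.sign(z) * z_adj_mag


def stouffer_combine(zs, weights=None) -> float:
    """Stouffer combination of signed z-scores; nan components are skipped."""
    zs = np.asarray(zs, dtype=float)
    if weights is None:
        weights = np.ones_like(zs)
    weights = np.asarray(weights, dtype=float)
    ok = np.isfinite(zs)
    if not ok.any():
        return 0.0
    zs, weights = zs[ok], weights[ok]
    return float((weights * zs).sum() / math.sqrt((weights**2).sum()))
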