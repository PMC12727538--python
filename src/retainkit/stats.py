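"""Shared statistical helpers: FDR, exact tests, proportion tests, correlation
comparison via the Fisher z-transform.

Standard procedures are delegated to scipy/statsmodels; only the pooled
two-proportion z (needed with and without continuity correction) and the
Fisher z comparison of correlations are written out, since neither is exposed
in the exact form required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_fdr",
    "bonferroni",
    "fisher_exact_2x2",
    "hypergeom_upper_tail",
    "two_proportion_z",
    "pearson_with_ci",
    "fisher_z_compare",
    "CorrelationEstimate",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="bonferroni")[1]


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value on a 2x2 contingency table."""
    return float(sps.fisher_exact(np.asarray(table), alternative=alternative)[1])


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def two_proportion_z(
    x1: int, n1: int, x2: int, n2: int,
    alternative: str = "larger",
    continuity: bool = False,
) -> tuple[float, float]:
    """Pooled two-sample test of equal proportions (prop.test family).

    Tests H0: p1 = p2 using the pooled-variance z statistic
    ``z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2))``. ``alternative`` is
    'larger' (p1 > p2), 'smaller', or 'two-sided'. ``continuity=True``
    applies the Yates correction 0.5*(1/n1 + 1/n2) to the difference.
    Returns (z, p).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    diff = p1 - p2
    if continuity:
        cc = 0.5 * (1 / n1 + 1 / n2)
        diff = np.sign(diff) * max(0.0, abs(diff) - cc)
    if se == 0:
        z = 0.0
    else:
        z = diff / se
    if alternative == "larger":
        p = sps.norm.sf(z)
    elif alternative == "smaller":
        p = sps.norm.cdf(z)
    elif alternative == "two-sided":
        p = 2 * sps.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), float(p)


@dataclass(frozen=True)
class CorrelationEstimate:
    r: float
    ci_low: float
    ci_high: float
    n: int
    p: float


def pearson_with_ci(x, y, conf: float = 0.95) -> CorrelationEstimate:
    """Pearson R with a Fisher-transform confidence interval.

    CI: ``tanh(atanh(r) ± z_crit / sqrt(n-3))``. Requires n >= 4 and
    non-degenerate variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    zcrit = sps.norm.ppf(0.5 + conf / 2)
    if abs(r) >= 1.0 - 1e-12:
        r = float(np.sign(r))
        lo = hi = r  # degenerate at the bound
    else:
        zr = np.arctanh(r)
        half = zcrit / np.sqrt(n - 3)
        lo, hi = np.tanh(zr - half), np.tanh(zr + half)
    return CorrelationEstimate(float(r), float(lo), float(hi), n, float(p))


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sided Fisher z-test that two independent Pearson correlations differ.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))``; returns (z, p).
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(z), float(2 * sps.norm.sf(abs(z)))
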