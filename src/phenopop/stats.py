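"""Tradeoff statistics: rank correlations, exact tests, CIs, BH adjustment.

These are the statistics tying the per-condition summaries together:
Spearman correlations for the bimodality-growth and viability-lag tradeoffs,
one-tailed Fisher exact tests for budded/unbudded counts, Wald proportion
confidence intervals, Welch/paired t tests, and Benjamini-Hochberg control
for multiple testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .growth import LagResult


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    p_approximate: bool     # t approximation is rough below n = 10


def spearman(x, y, exact: bool = False) -> CorrelationResult:
    """Spearman rank correlation (Pearson on average ranks, ties averaged).

    The p-value uses the t approximation; with ``exact`` (n <= 8) it is
    computed by full enumeration of rank permutations instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in ranks")
    rho, p = sps.spearmanr(x, y)
    if exact:
        if n > 8:
            raise ValueError("exact permutation p-value limited to n <= 8")
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        return CorrelationResult(rho=float(rho), n=n,
                                 p_value=count / total, p_approximate=False)
    return CorrelationResult(rho=float(rho), n=n, p_value=float(p),
                             p_approximate=n < 10)


def inverse_lag(lag: LagResult) -> float:
    """Growth-resumption score 1/lag; NaN propagates a censored lag."""
    if not lag.reached or lag.lag_h is None:
        return float("nan")
    return 1.0 / lag.lag_h


def fisher_exact_one_tailed(table, alternative: str = "greater") -> float:
    """One-tailed Fisher exact p by hypergeometric enumeration.

    ``alternative='greater'`` tests enrichment of the top-left cell (odds
    ratio > 1); the direction must be chosen by the caller from the
    scientific hypothesis (e.g. unbudded cells enriched in the low
    fraction).  Computed by direct summation of the hypergeometric pmf
    over the support.
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if not np.issubdtype(tab.dtype, np.integer):
        if not np.allclose(tab, np.round(tab)):
            raise ValueError("counts must be integers")
        tab = np.round(tab).astype(int)
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    a = int(tab[0, 0])
    r1 = int(tab[0].sum())
    c1 = int(tab[:, 0].sum())
    ntot = int(tab.sum())
    if r1 == 0 or c1 == 0 or r1 == ntot or c1 == ntot:
        return 1.0
    lo = max(0, r1 + c1 - ntot)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, ntot, c1, r1)
    if alternative == "greater":
        return float(pmf[support >= a].sum())
    return float(pmf[support <= a].sum())


def proportion_ci(k: int, n: int, level: float = 0.95,
                  method: str = "wald") -> tuple:
    """Confidence interval for a proportion, centred Wald by default.

    The Wald interval p +/- z*sqrt(p(1-p)/n) is truncated to [0, 1]; it is
    degenerate at k = 0 or k = n (an exact Clopper-Pearson interval is
    available via ``method='clopper-pearson'``).
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    if method == "clopper-pearson":
        from statsmodels.stats.proportion import proportion_confint
        lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
        return float(lo), float(hi)
    if method != "wald":
        raise ValueError(f"unknown method {method!r}")
    p = k / n
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / n)
    if k == 0 or k == n:
        import warnings
        warnings.warn("degenerate Wald interval at the boundary; consider "
                      "method='clopper-pearson'", stacklevel=2)
    return float(max(0.0, p - half)), float(min(1.0, p + half))


def t_test(a, b, paired: bool = False, alternative: str = "two-sided"
           ) -> tuple:
    """Welch t test (unpaired) or paired-difference t test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        if a.size < 2:
            raise ValueError("need at least 2 pairs")
        res = sps.ttest_rel(a, b, alternative=alternative)
    else:
        if a.size < 2 or b.size < 2:
            raise ValueError("need at least 2 values per group")
        res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (step-up), input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-D p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# condition panel assembly
# --------------------------------------------------------------------------

def assemble_condition_panel(rows) -> pd.DataFrame:
    """Stack per-condition summary dicts into a tradeoff panel table.

    Expected keys per row: condition, and any of dip, dip_p, mu_max,
    viable_fraction, lag_h, regime.  Missing values stay NaN and are
    dropped pairwise by :func:`tradeoff_correlation`.
    """
    panel = pd.DataFrame(list(rows))
    if "condition" not in panel.columns:
        raise ValueError("each row needs a 'condition' key")
    if panel["condition"].duplicated().any():
        raise ValueError("duplicate condition rows")
    return panel


def tradeoff_correlation(panel: pd.DataFrame, xcol: str, ycol: str
                         ) -> CorrelationResult:
    """Spearman correlation between two panel columns, NaNs dropped."""
    sub = panel[[xcol, ycol]].dropna()
    return spearman(sub[xcol].to_numpy(), sub[ycol].to_numpy())
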