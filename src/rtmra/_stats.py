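"""Small shared statistical primitives."""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def binom_tail_ge(k, n, p) -> np.ndarray | float:
    """One-sided upper binomial tail P[X >= k], X ~ Binom(n, p).

    Vectorized; the convention P[X >= 0] = 1 holds for k = 0.
    """
    return stats.binom.sf(np.asarray(k) - 1, n, p)


def _kw_h(values: np.ndarray, groups: np.ndarray) -> float:
    """Kruskal–Wallis H with midrank ties (no chi-square lookup)."""
    r = stats.rankdata(values)
    n = len(values)
    h = 0.0
    for g in np.unique(groups):
        rg = r[groups == g]
        h += rg.sum() ** 2 / len(rg)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else np.nan


def kruskal_exact_or_approx(groups: list[np.ndarray], exact_max_n: int = 8):
    """Kruskal–Wallis test; exact enumeration over group assignments when
    the total sample size is small, chi-square approximation otherwise.

    Returns (H, p).  The exact p is the fraction of equally likely
    assignments of the pooled observations to groups of the observed
    sizes whose H is >= the observed H (within numerical tolerance).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    labels = np.repeat(np.arange(len(groups)), sizes)
    n = len(pooled)
    if np.ptp(pooled) == 0:  # all observations tied: no evidence either way
        return 0.0, 1.0
    h_obs = _kw_h(pooled, labels)
    if np.isnan(h_obs):
        return np.nan, np.nan
    if n <= exact_max_n and len(groups) == 2:
        idx = np.arange(n)
        n1 = sizes[0]
        count = total = 0
        for subset in combinations(idx, n1):
            lab = np.ones(n, dtype=int)
            lab[list(subset)] = 0
            h = _kw_h(pooled, lab)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
        return float(h_obs), count / total
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Effect size d = t * sqrt((n1 + n2) / (n1 * n2))."""
    return float(t * np.sqrt((n1 + n2) / (n1 * n2)))
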