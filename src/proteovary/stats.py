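"""Small shared statistics used across pipeline stages."""

from __future__ import annotations

import numpy as np
from scipy import stats


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    NaN entries are ignored for ranking and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    m = pm.size
    if m == 0:
        return q
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[mask] = adj
    return q


def fisher_combine(pvalues) -> tuple[float, int, float]:
    """Fisher's method: chi2 = -2 sum(log p), df = 2k, combined p.

    Zero p-values are clamped to the smallest positive float.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values to combine")
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0)
    chi2 = float(-2.0 * np.sum(np.log(p)))
    df = 2 * int(p.size)
    combined = float(stats.chi2.sf(chi2, df))
    return chi2, df, combined


def cohens_d(x, y) -> float:
    """Cohen's d with pooled (n-1 weighted) standard deviation, mean(x)-mean(y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        return float("nan")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    if pooled == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(pooled))


def empirical_p(null: np.ndarray, observed: float) -> float:
    """Plus-one permutation p-value: (1 + #null >= observed) / (1 + n)."""
    null = np.asarray(null, dtype=float)
    return float((1.0 + np.sum(null >= observed)) / (1.0 + null.size))


def masked_pearson(x: np.ndarray, y: np.ndarray, min_overlap: int = 6):
    """Pearson r over jointly non-missing entries.

    Returns (r, n_overlap); r is NaN when overlap < min_overlap or either
    vector is constant on the overlap.
    """
    mask = ~np.isnan(x) & ~np.isnan(y)
    n = int(mask.sum())
    if n < min_overlap:
        return float("nan"), n
    xv, yv = x[mask], y[mask]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return float("nan"), n
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r, n


def observed_vs_null_ttest(observed, null) -> float:
    """Two-sided t-test of observed correlation values against a permutation null.

    With >= 2 observed values a Welch two-sample t-test is used; with a single
    observed value the one-sample t-test of the null distribution against that
    value is returned.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.size >= 2:
        return float(stats.ttest_ind(observed, null, equal_var=False).pvalue)
    return float(stats.ttest_1samp(null, observed[0]).pvalue)
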