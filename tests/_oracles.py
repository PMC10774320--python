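"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately naive (explicit loops, closed forms,
exhaustive enumeration) and shares no code with the package internals.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def running_sum_es(ranked_scores: np.ndarray, hit_mask: np.ndarray,
                   weight_exponent: float = 1.0,
                   hit_weights: np.ndarray | None = None) -> float:
    """Step-by-step weighted KS enrichment score over an already-ranked list.

    ``hit_weights`` (aligned with the hit positions in ranked order) default
    to 1. Ties between the positive and negative extremum resolve positive.
    """
    n = len(ranked_scores)
    k = int(hit_mask.sum())
    if hit_weights is None:
        hit_weights = np.ones(k)
    inc = np.abs(ranked_scores[hit_mask]) ** weight_exponent * hit_weights
    if inc.sum() == 0:
        inc = hit_weights.astype(float)
    inc = inc / inc.sum()
    walk, best_pos, best_neg = 0.0, 0.0, 0.0
    hit_iter = iter(inc)
    for i in range(n):
        if hit_mask[i]:
            walk += next(hit_iter)
        else:
            walk -= 1.0 / (n - k)
        best_pos = max(best_pos, walk)
        best_neg = min(best_neg, walk)
    return best_pos if best_pos >= -best_neg else best_neg


def exhaustive_null(ranked_scores: np.ndarray, k: int,
                    weight_exponent: float = 1.0) -> np.ndarray:
    """ES of every possible placement of a k-set in the ranked signature."""
    n = len(ranked_scores)
    out = []
    for pos in combinations(range(n), k):
        mask = np.zeros(n, dtype=bool)
        mask[list(pos)] = True
        out.append(running_sum_es(ranked_scores, mask, weight_exponent))
    return np.array(out)


def exhaustive_pvalue(ranked_scores: np.ndarray, k: int, es: float,
                      weight_exponent: float = 1.0) -> float:
    null = exhaustive_null(ranked_scores, k, weight_exponent)
    if es > 0:
        return float(np.mean(null >= es))
    if es < 0:
        return float(np.mean(null <= es))
    return 1.0


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Closed-form Welch statistic of b versus a."""
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (b.mean() - a.mean()) / np.sqrt(va + vb)


def ols_slope_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(alpha, beta, t, p) of simple OLS by the textbook formulas."""
    from scipy import stats

    n = len(x)
    xm, ym = x.mean(), y.mean()
    beta = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    alpha = ym - beta * xm
    resid = y - alpha - beta * x
    s2 = np.sum(resid**2) / (n - 2)
    se = np.sqrt(s2 / np.sum((x - xm) ** 2))
    t = beta / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return alpha, beta, t, p


def bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask, written out longhand."""
    m = len(pvals)
    order = np.argsort(pvals)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = np.where(pvals[order] <= thresh)[0]
    mask = np.zeros(m, dtype=bool)
    if len(passed):
        mask[order[: passed.max() + 1]] = True
    return mask


def cooks_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cook's D from leverages and residuals of the simple linear fit."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    h = np.diag(H)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    e = y - X @ beta
    s2 = np.sum(e**2) / (n - 2)
    return e**2 * h / (2 * s2 * (1 - h) ** 2)


def vif_by_ols(acts: np.ndarray) -> np.ndarray:
    """VIF of each row of ``acts`` against the others via direct OLS."""
    m, n = acts.shape
    out = np.empty(m)
    for i in range(m):
        y = acts[i]
        X = np.column_stack([np.ones(n), np.delete(acts, i, axis=0).T])
        coef = np.linalg.lstsq(X, y, rcond=None)[0]
        r2 = 1 - np.sum((y - X @ coef) ** 2) / np.sum((y - y.mean()) ** 2)
        out[i] = 1.0 / (1.0 - r2)
    return out
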