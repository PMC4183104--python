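"""Independent brute-force reference implementations used only by tests.

These deliberately use naive enumeration / explicit summation so they share
no code path with the package: F by per-index turning-point lookback and
lookahead, D by an explicit double loop over sorted pairs, Pearson r by the
textbook sum formula, Type III ANOVA by model-comparison least squares, and
hierarchical regression by raw normal equations on z-scored data.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def oracle_fluctuation(window, lo: float, hi: float) -> float:
    """Explicit turning-point enumeration over every interior index.

    Index k is a turning point when the nearest differing values to its left
    and right lie on the same side (local extremum, flat runs included);
    every index of a flat extremum qualifies, which changes nothing because
    within-plateau segments contribute zero.
    """
    w = list(map(float, window))
    m = len(w)
    R = hi - lo
    tps = {0, m - 1}
    for k in range(1, m - 1):
        li = next((i for i in range(k - 1, -1, -1) if w[i] != w[k]), None)
        ri = next((j for j in range(k + 1, m) if w[j] != w[k]), None)
        if li is not None and ri is not None and (w[k] - w[li]) * (w[ri] - w[k]) < 0:
            tps.add(k)
    order = sorted(tps)
    total = 0.0
    for a, b in zip(order[:-1], order[1:]):
        total += abs(w[b] - w[a]) / (b - a)
    return total / (R * (m - 1))


def oracle_distribution(window, lo: float, hi: float) -> float:
    """Explicit pairwise loop over the sorted window."""
    x = sorted(map(float, window))
    m = len(x)
    R = hi - lo
    deficit = 0.0
    total = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            ideal = (j - i) * R / (m - 1)
            actual = x[j] - x[i]
            if actual < ideal:
                deficit += ideal - actual
            total += ideal
    return 1.0 - deficit / total


def oracle_pearson(x, y) -> tuple[float, float]:
    """Textbook sum-formula Pearson r with two-sided p from the t distribution."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    r = num / den
    t = r * np.sqrt((n - 2) / (1 - r * r)) if abs(r) < 1 else np.inf
    p = 2 * sps.t.sf(abs(t), n - 2)
    return float(r), float(p)


def oracle_anova_2x2(y, a_high, b_high) -> dict[str, dict[str, float]]:
    """Type III 2x2 ANOVA by model comparison with sum-to-zero coding."""
    y = np.asarray(y, float)
    A = np.where(np.asarray(a_high), 1.0, -1.0)
    B = np.where(np.asarray(b_high), 1.0, -1.0)
    X = np.column_stack([np.ones(y.size), A, B, A * B])

    def sse(cols):
        beta, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
        resid = y - X[:, cols] @ beta
        return float(resid @ resid)

    full = sse([0, 1, 2, 3])
    df_err = y.size - 4
    out = {}
    for name, col in (("a", 1), ("b", 2), ("a:b", 3)):
        reduced = sse([c for c in range(4) if c != col])
        ss = reduced - full
        F = (ss / 1.0) / (full / df_err)
        out[name] = {
            "F": F,
            "p": float(sps.f.sf(F, 1, df_err)),
            "partial_eta_sq": ss / (ss + full),
        }
    return out


def oracle_posthoc_t(g1, g2) -> tuple[float, float, float]:
    """Pooled-variance two-sample t, p, and Cohen's d from textbook formulas."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    n1, n2 = g1.size, g2.size
    v1 = ((g1 - g1.mean()) ** 2).sum() / (n1 - 1)
    v2 = ((g2 - g2.mean()) ** 2).sum() / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (g1.mean() - g2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
    d = (g1.mean() - g2.mean()) / np.sqrt(sp2)
    return float(t), float(p), float(d)


def oracle_hierarchical(y, block_arrays: list[list[np.ndarray]]):
    """Nested OLS on z-scored variables via raw normal equations.

    Returns per block: standardized betas (in entry order), R^2, dR^2,
    F-change, p-change.
    """

    def z(v):
        v = np.asarray(v, float)
        return (v - v.mean()) / v.std(ddof=1)

    yz = z(y)
    n = yz.size
    cols: list[np.ndarray] = []
    out = []
    r2_prev = 0.0
    for block in block_arrays:
        cols.extend(z(v) for v in block)
        X = np.column_stack([np.ones(n)] + cols)
        beta = np.linalg.solve(X.T @ X, X.T @ yz)
        resid = yz - X @ beta
        r2 = 1.0 - (resid @ resid) / ((yz - yz.mean()) @ (yz - yz.mean()))
        p_k = len(cols)
        q_k = len(block)
        f_change = (r2 - r2_prev) * (n - p_k - 1) / ((1 - r2) * q_k)
        out.append(
            {
                "beta": beta[1:].copy(),
                "r_squared": float(r2),
                "r_squared_change": float(r2 - r2_prev),
                "f_change": float(f_change),
                "p_change": float(sps.f.sf(f_change, q_k, n - p_k - 1)),
            }
        )
        r2_prev = r2
    return out
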