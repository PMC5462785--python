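"""Independent reference implementations used by the test suite.

These deliberately share no code with the package: the surface oracle is an
exhaustive dynamic-programming search over all feasible surfaces, the
statistics oracles are textbook closed forms.
"""

from __future__ import annotations

import itertools

import numpy as np


def column_objective(cost_col: np.ndarray, k: int) -> float:
    """Two-sided misassignment cost of placing the surface at ``k``."""
    return float(np.sum(1.0 - cost_col[:k]) + np.sum(cost_col[k:]))


def dp_surface_optimum(cost: np.ndarray, delta: int) -> float:
    """Exact optimal objective over all surfaces with ``|dz| <= delta``
    between 4-neighbour columns, by exhaustive DP over B-scans.

    The state enumerates every feasible A-scan profile of one B-scan, so this
    is an exhaustive search over the feasible set (suitable only for tiny
    grids).
    """
    nb, na, nz = cost.shape
    f = np.empty((nb, na, nz))
    for b in range(nb):
        for a in range(na):
            for k in range(nz):
                f[b, a, k] = column_objective(cost[b, a], k)
    states = np.array(
        [
            s
            for s in itertools.product(range(nz), repeat=na)
            if all(abs(s[i] - s[i + 1]) <= delta for i in range(na - 1))
        ]
    )
    state_cost = lambda b: f[b, np.arange(na)[None, :], states].sum(axis=1)
    best = state_cost(0)
    compat = np.abs(states[:, None, :] - states[None, :, :]).max(axis=2) <= delta
    for b in range(1, nb):
        prev = np.where(compat, best[None, :], np.inf).min(axis=1)
        best = prev + state_cost(b)
    return float(best.min())


def anova_closed_form(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA by explicit sums of squares."""
    from scipy import stats

    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    if ss_within == 0:
        return (0.0, 1.0) if ss_between == 0 else (np.inf, 0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients via the normal equations."""
    return np.linalg.solve(X.T @ X, X.T @ y)
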