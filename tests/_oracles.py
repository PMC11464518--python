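"""Independent brute-force / closed-form oracles used across the suite.

Everything here is deliberately naive and separate from the package
implementation paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ols_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and n-2 residual SD from the sum formulas."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (intercept + slope * x)
    residual_sd = np.sqrt((resid**2).sum() / (n - 2))
    return float(slope), float(intercept), float(residual_sd)


def cpm_brute_force(graph, k: int) -> set[frozenset]:
    """Clique-percolation communities by exhaustive k-subset enumeration."""
    nodes = list(graph.nodes)
    kcliques = [
        frozenset(s)
        for s in combinations(nodes, k)
        if all(graph.has_edge(u, v) for u, v in combinations(s, 2))
    ]
    # percolation graph: cliques adjacent iff they share k-1 nodes
    parent = list(range(len(kcliques)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(len(kcliques)), 2):
        if len(kcliques[i] & kcliques[j]) == k - 1:
            parent[find(i)] = find(j)
    comps: dict[int, set] = {}
    for i, c in enumerate(kcliques):
        comps.setdefault(find(i), set()).update(c)
    return {frozenset(c) for c in comps.values()}


def auc_pair_counting(scores: np.ndarray, events: np.ndarray) -> float:
    """AUC by exhaustive case/control pair comparison (ties worth 1/2)."""
    pos = scores[events == 1]
    neg = scores[events == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def breslow_neg_log_pl(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Naive Breslow partial likelihood for a single covariate."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        at_risk = time >= t
        ll += beta * x[dead].sum()
        ll -= dead.sum() * np.log(np.exp(beta * x[at_risk]).sum())
    return -ll


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax objective: sum of column variances of squared loadings."""
    sq = loadings**2
    return float((sq.var(axis=0)).sum())


def rotate_2d(loadings: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return loadings @ np.array([[c, -s], [s, c]])
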