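"""Group-level correlation networks and k-clique percolation communities.

The population network has physiological variables as nodes and an edge
wherever the pairwise Pearson correlation is significant (optionally
Bonferroni-corrected over all C(p, 2) pairs); edge weight is the Pearson r.
Overlapping communities are detected by clique percolation: communities are
unions of k-cliques chained through (k-1)-node overlaps. Community
detection operates on the binary adjacency (weights ignored); an optional
absolute-weight pre-filter can threshold edges first.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import k_clique_communities as _nx_kcc
from scipy import stats

__all__ = ["CommunityPartition", "correlation_network", "k_clique_communities"]


@dataclass(frozen=True)
class CommunityPartition:
    """Overlapping node communities at clique size k."""

    k: int
    communities: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        for c in self.communities:
            if len(c) < self.k:
                raise ValueError("every community must contain >= k nodes")

    def as_sorted_lists(self) -> list[list]:
        return sorted(sorted(c) for c in self.communities)

    def to_dict(self) -> dict:
        return {"k": self.k, "communities": self.as_sorted_lists()}


def correlation_network(
    group: pd.DataFrame,
    variables: Sequence[str],
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> nx.Graph:
    """Pearson correlation network of one patient group.

    Pairwise-complete rows per pair; edge (A, B) iff the two-tailed p-value
    is below ``alpha / C(p, 2)`` (Bonferroni) or ``alpha``; weight is r.
    """
    variables = sorted(variables)
    missing = [v for v in variables if v not in group.columns]
    if missing:
        raise ValueError(f"group table lacks variables: {missing}")
    n_pairs = math.comb(len(variables), 2)
    if n_pairs == 0:
        raise ValueError("need at least two variables")
    threshold = alpha / n_pairs if bonferroni else alpha
    g = nx.Graph()
    g.add_nodes_from(variables)
    g.graph.update(alpha=alpha, bonferroni=bonferroni, threshold=threshold)
    cols = {v: group[v].to_numpy(dtype=float) for v in variables}
    for a, b in combinations(variables, 2):
        x, y = cols[a], cols[b]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            warnings.warn(
                f"pair ({a}, {b}): fewer than 3 complete rows; skipped",
                stacklevel=2,
            )
            continue
        xs, ys = x[ok], y[ok]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            warnings.warn(
                f"pair ({a}, {b}): constant variable; skipped", stacklevel=2
            )
            continue
        r, p = stats.pearsonr(xs, ys)
        if p < threshold:
            g.add_edge(a, b, weight=float(r), p_value=float(p))
    return g


def k_clique_communities(
    graph: nx.Graph,
    k: int,
    weight_threshold: float | None = None,
) -> CommunityPartition:
    """Clique-percolation communities of ``graph`` at clique size ``k``.

    ``k`` is a required explicit choice. When ``weight_threshold`` is given,
    edges with |weight| below it are dropped before detection; detection
    itself is on the binary adjacency. A ``k`` above the maximum clique size
    yields an empty partition.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    g = graph
    if weight_threshold is not None:
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        g.add_edges_from(
            (u, v, d)
            for u, v, d in graph.edges(data=True)
            if abs(d.get("weight", 1.0)) >= weight_threshold
        )
    comms = tuple(frozenset(c) for c in _nx_kcc(g, k))
    return CommunityPartition(k=k, communities=comms)
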