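"""Graph-theoretic properties of binary functional networks.

Nodal metrics on the thresholded (unweighted) adjacency: degree,
clustering coefficient, nodal/characteristic path length, local
efficiency and betweenness centrality (endpoints excluded,
unnormalized, one count per unordered pair).  Hemispheric summaries
average each nodal metric over 15 key electrodes per hemisphere and
take left-minus-right differences; the characteristic path length L is
additionally computed over the 30-electrode union, with distances
measured on the full graph and unreachable pairs excluded (count
logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._montage import LEFT_KEY_15, RIGHT_KEY_15
from .connectivity import BinaryNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "NodeMetrics",
    "HemisphereSummary",
    "node_metrics",
    "global_path_length",
    "hemisphere_summary",
]

#: Nodal metric short names, in canonical order (degree, clustering,
#: path length, local efficiency, betweenness).
METRIC_KEYS = ("K", "C", "L", "E", "BC")


@dataclass
class NodeMetrics:
    """Per-node metrics; isolated nodes have NaN nodal path length."""

    channel_names: tuple[str, ...]
    degree: np.ndarray
    clustering: np.ndarray
    path_length: np.ndarray
    local_efficiency: np.ndarray
    betweenness: np.ndarray

    def by_key(self, key: str) -> np.ndarray:
        return {
            "K": self.degree,
            "C": self.clustering,
            "L": self.path_length,
            "E": self.local_efficiency,
            "BC": self.betweenness,
        }[key]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "degree": self.degree,
                "clustering": self.clustering,
                "path_length": self.path_length,
                "local_efficiency": self.local_efficiency,
                "betweenness": self.betweenness,
            },
            index=list(self.channel_names),
        )


@dataclass
class HemisphereSummary:
    """Hemispheric means of the five nodal metrics, the 30-electrode
    characteristic path length, and left-minus-right differences."""

    KL: float; CL: float; LL: float; EL: float; BCL: float
    KR: float; CR: float; LR: float; ER: float; BCR: float
    L: float
    KD: float; CD: float; LD: float; ED: float; BCD: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _graph(net: BinaryNetwork) -> nx.Graph:
    A = np.asarray(net.A)
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have no self loops")
    G = nx.from_numpy_array(A)
    return G


def node_metrics(net: BinaryNetwork) -> NodeMetrics:
    """All five nodal metrics of a binary network."""
    G = _graph(net)
    n = G.number_of_nodes()
    degree = np.array([G.degree(v) for v in range(n)], dtype=float)
    clustering = np.array([nx.clustering(G, v) for v in range(n)], dtype=float)

    path_length = np.full(n, np.nan)
    for v in range(n):
        dists = nx.single_source_shortest_path_length(G, v)
        del dists[v]
        if dists:
            path_length[v] = float(np.mean(list(dists.values())))

    local_eff = np.zeros(n)
    for v in range(n):
        neigh = list(G.neighbors(v))
        if len(neigh) >= 2:
            local_eff[v] = nx.global_efficiency(G.subgraph(neigh))

    bc = nx.betweenness_centrality(G, normalized=False)
    betweenness = np.array([bc[v] for v in range(n)], dtype=float)

    return NodeMetrics(
        channel_names=net.channel_names,
        degree=degree,
        clustering=clustering,
        path_length=path_length,
        local_efficiency=local_eff,
        betweenness=betweenness,
    )


def global_path_length(net: BinaryNetwork, nodes=None, return_excluded: bool = False):
    """Characteristic path length over ``nodes`` (channel names or
    indices; default all), distances on the full graph.

    Unreachable ordered pairs are excluded from the mean; their count is
    logged (and returned when ``return_excluded``).
    """
    G = _graph(net)
    if nodes is None:
        idx = list(range(G.number_of_nodes()))
    else:
        nodes = list(nodes)
        if not nodes:
            raise ValueError("empty node subset")
        lookup = {name: i for i, name in enumerate(net.channel_names)}
        idx = [lookup[v] if isinstance(v, str) else int(v) for v in nodes]
    if len(idx) < 2:
        raise ValueError("path length needs at least two nodes")
    dsum, n_pairs, excluded = 0.0, 0, 0
    idx_set = set(idx)
    for v in idx:
        dists = nx.single_source_shortest_path_length(G, v)
        for u in idx:
            if u == v:
                continue
            if u in dists:
                dsum += dists[u]
                n_pairs += 1
            else:
                excluded += 1
    if excluded:
        logger.info("path length: excluded %d unreachable ordered pairs", excluded)
    L = dsum / n_pairs if n_pairs else float("nan")
    if return_excluded:
        return L, excluded
    return L


def hemisphere_summary(
    metrics: NodeMetrics,
    net: BinaryNetwork,
    left=LEFT_KEY_15,
    right=RIGHT_KEY_15,
) -> HemisphereSummary:
    """Hemispheric means and left-minus-right differences.

    Nodal means use NaN-aware averaging (isolated nodes contribute no
    path-length term); L is the characteristic path length over the
    30-electrode union on the full graph.
    """
    left, right = tuple(left), tuple(right)
    for name, side in (("left", left), ("right", right)):
        if len(side) != 15:
            raise ValueError(f"{name} hemisphere set must have 15 electrodes, got {len(side)}")
    if set(left) & set(right):
        raise ValueError("hemisphere sets must be disjoint")
    lookup = {n: i for i, n in enumerate(metrics.channel_names)}
    missing = [c for c in left + right if c not in lookup]
    if missing:
        raise ValueError(f"hemisphere electrodes not in montage: {missing}")
    li = [lookup[c] for c in left]
    ri = [lookup[c] for c in right]

    def side_means(idx):
        return {k: float(np.nanmean(metrics.by_key(k)[idx])) for k in METRIC_KEYS}

    lm, rm = side_means(li), side_means(ri)
    L = global_path_length(net, nodes=list(left + right))
    return HemisphereSummary(
        KL=lm["K"], CL=lm["C"], LL=lm["L"], EL=lm["E"], BCL=lm["BC"],
        KR=rm["K"], CR=rm["C"], LR=rm["L"], ER=rm["E"], BCR=rm["BC"],
        L=L,
        KD=lm["K"] - rm["K"], CD=lm["C"] - rm["C"], LD=lm["L"] - rm["L"],
        ED=lm["E"] - rm["E"], BCD=lm["BC"] - rm["BC"],
    )
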