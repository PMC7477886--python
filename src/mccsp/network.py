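"""Weighted DAG, log-reciprocal weight transform, K-shortest-paths ranking, PIS.

The pathway effect of a chain SNP -> M1 -> ... -> disease is the product of
its edge strengths r_ij.  With the transform r'_ij = log(1/r_ij) the product
becomes a sum, so the largest-effect chains are exactly the smallest-weight
source->sink paths, found here with a deviation-path (Yen) search whose
shortest-path subroutine relaxes edges in topological order — valid on DAGs
even with negative weights (raw mutual information can exceed 1, giving
log(1/r) < 0).
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .correlations import DependenceMethod, edge_strength
from .exceptions import ConfigurationError, DegenerateInputError, NetworkStructureError

__all__ = [
    "DirectedNetwork",
    "WeightedNetwork",
    "Pathway",
    "PathwayRanking",
    "weight_transform",
    "estimate_weighted_network",
    "k_shortest_paths",
    "enumerate_all_simple_paths",
    "pathway_effect",
    "compute_pis",
    "rank_pathways",
]

#: strengths at or below this are treated as absent edges (infinite weight)
EPSILON_STRENGTH = 1e-12

#: refuse full pathway enumeration (needed for q50) beyond this many paths
MAX_ENUMERATED_PATHS = 1_000_000


@dataclass(frozen=True)
class DirectedNetwork:
    """A validated DAG with one designated source (variant) and sink (disease).

    Node and edge declaration order is canonicalised away, so downstream
    results do not depend on input ordering.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    source: str
    sink: str

    def __init__(self, nodes, edges, source, sink):
        nodes = tuple(str(n) for n in nodes)
        edges = tuple((str(a), str(b)) for a, b in edges)
        if len(set(nodes)) != len(nodes):
            raise NetworkStructureError("duplicate node names")
        if len(set(edges)) != len(edges):
            dupes = sorted({e for e in edges if edges.count(e) > 1})
            raise NetworkStructureError(f"duplicate edges: {dupes}")
        declared = set(nodes)
        for a, b in edges:
            if a not in declared or b not in declared:
                raise NetworkStructureError(f"edge ({a}, {b}) uses undeclared node")
        for name, val in (("source", source), ("sink", sink)):
            if val not in declared:
                raise NetworkStructureError(f"{name} node '{val}' is not a declared node")
        if source == sink:
            raise NetworkStructureError("source and sink must differ")
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise NetworkStructureError(f"network contains a directed cycle: {cycle}")
        if g.in_degree(source) != 0:
            raise NetworkStructureError(f"source '{source}' has incoming edges")
        if g.out_degree(sink) != 0:
            raise NetworkStructureError(f"sink '{sink}' has outgoing edges")
        object.__setattr__(self, "nodes", tuple(sorted(nodes)))
        object.__setattr__(self, "edges", tuple(sorted(edges)))
        object.__setattr__(self, "source", str(source))
        object.__setattr__(self, "sink", str(sink))

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self) -> list[str]:
        # lexicographic among ready nodes, for deterministic iteration
        return list(nx.lexicographical_topological_sort(self.graph()))


def weight_transform(r: float) -> float:
    """Search weight r' = log(1/r) (natural log); 0 at r = 1, decreasing in r.

    Strengths above 1 (raw mutual information) are accepted and yield
    negative weights; the path search handles those on DAGs.
    """
    if r <= 0:
        raise DegenerateInputError(f"strength must be positive, got {r}")
    return -math.log(r)


@dataclass
class WeightedNetwork:
    """A DirectedNetwork plus per-edge strength r_ij and weight log(1/r_ij)."""

    network: DirectedNetwork
    strength: dict[tuple[str, str], float]
    weight: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_strengths(cls, network: DirectedNetwork,
                       strength: dict[tuple[str, str], float],
                       eps: float = EPSILON_STRENGTH) -> "WeightedNetwork":
        missing = [e for e in network.edges if e not in strength]
        if missing:
            raise NetworkStructureError(f"no strength for edges: {missing}")
        weight = {}
        for e in network.edges:
            r = strength[e]
            if r < 0:
                raise DegenerateInputError(f"negative strength {r} on edge {e}")
            weight[e] = weight_transform(r) if r > eps else math.inf
        return cls(network, dict(strength), weight)


@dataclass(frozen=True)
class Pathway:
    """One source->sink chain with its effect, total weight, and PIS."""

    nodes: tuple[str, ...]
    effect: float
    total_weight: float
    pis: float | None = None


@dataclass(frozen=True)
class PathwayRanking:
    """K-shortest pathways (ascending weight) plus the all-path median effect q50."""

    pathways: tuple[Pathway, ...]
    q50: float | None
    n_total_paths: int


def _adjacency(w: WeightedNetwork) -> dict[str, list[tuple[str, float]]]:
    adj: dict[str, list[tuple[str, float]]] = {n: [] for n in w.network.nodes}
    for (a, b) in w.network.edges:
        wt = w.weight[(a, b)]
        if math.isfinite(wt):
            adj[a].append((b, wt))
    for n in adj:
        adj[n].sort()
    return adj


def _dag_shortest(adj, topo_index, topo, src, sink,
                  banned_nodes, banned_edges):
    """Lexicographically-smallest minimum-weight path src->sink, or None.

    Straight relaxation in topological order; correct for any edge weights.
    """
    dist = {src: 0.0}
    path = {src: (src,)}
    for u in topo[topo_index[src]:]:
        if u not in dist or u in banned_nodes:
            continue
        du, pu = dist[u], path[u]
        for v, wt in adj[u]:
            if v in banned_nodes or (u, v) in banned_edges:
                continue
            nd = du + wt
            cand = pu + (v,)
            if v not in dist or nd < dist[v] or (nd == dist[v] and cand < path[v]):
                dist[v] = nd
                path[v] = cand
    return path.get(sink)


def _path_weight(w: WeightedNetwork, nodes: tuple[str, ...]) -> float:
    # always summed in path order so identical paths get bit-identical weights
    return sum(w.weight[(a, b)] for a, b in zip(nodes[:-1], nodes[1:]))


def k_shortest_paths(w: WeightedNetwork, K: int) -> list[Pathway]:
    """Up to K loopless source->sink paths in ascending total weight.

    Ties are broken lexicographically on the node-name sequence.  Returns an
    empty list when no finite-weight path exists.
    """
    if K < 1:
        raise ConfigurationError(f"K must be a positive integer, got {K}")
    net = w.network
    adj = _adjacency(w)
    topo = net.topological_order()
    topo_index = {n: i for i, n in enumerate(topo)}
    first = _dag_shortest(adj, topo_index, topo, net.source, net.sink,
                          frozenset(), frozenset())
    if first is None:
        return []
    accepted: list[tuple[str, ...]] = [first]
    candidates: list[tuple[float, tuple[str, ...]]] = []
    seen = {first}
    while len(accepted) < K:
        prev = accepted[-1]
        for i in range(len(prev) - 1):
            root = prev[: i + 1]
            spur = prev[i]
            banned_edges = {(p[i], p[i + 1]) for p in accepted
                            if len(p) > i + 1 and p[: i + 1] == root}
            banned_nodes = set(root[:-1])
            spur_path = _dag_shortest(adj, topo_index, topo, spur, net.sink,
                                      banned_nodes, banned_edges)
            if spur_path is None:
                continue
            total = root[:-1] + spur_path
            if total not in seen:
                seen.add(total)
                heapq.heappush(candidates, (_path_weight(w, total), total))
        if not candidates:
            break
        _, nxt = heapq.heappop(candidates)
        accepted.append(nxt)
    # present in (weight, lexicographic) order; deviation order already is,
    # but re-sorting guards against float ties discovered out of order
    accepted.sort(key=lambda p: (_path_weight(w, p), p))
    return [Pathway(p, effect=pathway_effect(p, w), total_weight=_path_weight(w, p))
            for p in accepted[:K]]


def enumerate_all_simple_paths(net: DirectedNetwork) -> list[tuple[str, ...]]:
    """All simple source->sink node chains, in lexicographic order."""
    g = net.graph()
    return sorted(tuple(p) for p in nx.all_simple_paths(g, net.source, net.sink))


def count_paths(net: DirectedNetwork) -> int:
    """Number of distinct source->sink paths (linear-time DP over the DAG)."""
    counts = {net.source: 1}
    g = net.graph()
    for u in net.topological_order():
        c = counts.get(u, 0)
        if c == 0:
            continue
        for v in g.successors(u):
            counts[v] = counts.get(v, 0) + c
    return counts.get(net.sink, 0)


def pathway_effect(nodes, w: WeightedNetwork) -> float:
    """Product of edge strengths along the chain; equals exp(-total weight)."""
    effect = 1.0
    for a, b in zip(nodes[:-1], nodes[1:]):
        if (a, b) not in w.strength:
            raise NetworkStructureError(f"chain uses missing edge ({a}, {b})")
        effect *= w.strength[(a, b)]
    return effect


def compute_pis(effects) -> np.ndarray:
    """Pathway importance scores: each effect divided by the median effect q50."""
    effects = np.asarray(effects, dtype=np.float64)
    if effects.size < 1:
        raise ConfigurationError("need at least one pathway effect")
    if (effects < 0).any():
        raise DegenerateInputError("pathway effects must be nonnegative")
    q50 = float(np.median(effects))
    if q50 == 0.0:
        raise DegenerateInputError("median pathway effect is zero; PIS undefined")
    return effects / q50


def estimate_weighted_network(data, net: DirectedNetwork,
                              method: DependenceMethod | str,
                              cfg=None, eps: float = EPSILON_STRENGTH) -> WeightedNetwork:
    """Estimate every edge's strength from a samples x nodes data matrix.

    ``data`` is a pandas DataFrame (or mapping of column name -> vector)
    whose columns cover the network's node names; n >= 10 rows required.
    """
    cols = set(data.keys()) if hasattr(data, "keys") else set()
    missing = sorted(set(net.nodes) - cols)
    if missing:
        raise ConfigurationError(f"data matrix lacks columns for nodes: {missing}")
    n = len(np.asarray(data[net.source]))
    if n < 10:
        raise DegenerateInputError(f"need at least 10 samples, got {n}")
    strengths = {}
    for (a, b) in net.edges:
        try:
            strengths[(a, b)] = edge_strength(np.asarray(data[a], dtype=float),
                                              np.asarray(data[b], dtype=float),
                                              method, cfg)
        except Exception as exc:
            raise type(exc)(f"estimating edge ({a}, {b}): {exc}") from exc
    return WeightedNetwork.from_strengths(net, strengths, eps=eps)


def rank_pathways(data, net: DirectedNetwork, method: DependenceMethod | str,
                  K: int | None = None, cfg=None) -> PathwayRanking:
    """Full pipeline: estimate strengths, rank chains, attach effects and PIS.

    q50 is the median effect over *all* Q source->sink pathways (not just the
    K returned ones); when the network has more than 10^6 paths, enumeration
    is skipped and PIS is reported as unavailable.
    """
    w = estimate_weighted_network(data, net, method, cfg)
    q = count_paths(net)
    if q < 1:
        raise NetworkStructureError("network has no source->sink path")
    q50: float | None
    if q <= MAX_ENUMERATED_PATHS:
        all_effects = [pathway_effect(p, w) for p in enumerate_all_simple_paths(net)]
        q50 = float(np.median(all_effects))
    else:
        warnings.warn(f"{q} pathways exceed the enumeration limit; PIS unavailable",
                      RuntimeWarning, stacklevel=2)
        q50 = None
    k = q if K is None else min(K, q)
    paths = k_shortest_paths(w, k)
    if q50 is not None and q50 > 0:
        paths = [Pathway(p.nodes, p.effect, p.total_weight, pis=p.effect / q50)
                 for p in paths]
    return PathwayRanking(tuple(paths), q50, q)
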