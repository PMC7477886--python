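"""Structural-equation benchmark for comparing the six integration methods.

The benchmark plants 4 high-effect source->sink pathways (edge strengths
drawn from U(0.75, 1)) in a 56-node / 82-edge DAG whose remaining edges are
weak (U(0, 0.25)).  Node values are generated in topological order as
x_child = mu + sum_p beta_p * phi_p(x_parent) + eps with Gaussian noise, every
node standardised to mean 0 / variance 1 on the population, and the target
corr(phi(parent), child) = w enforced exactly (up to Monte-Carlo error) by
solving beta from the empirical correlation matrix of the transformed
parents.  Replicates subsample the population without replacement, re-estimate
the weighted network with one of the six dependence measures, and are scored
by whether the K-shortest-path search recovers the true top-4 pathways in
exact order ("all-right") or as a set ("range-right").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlations import DependenceMethod
from .exceptions import ConfigurationError, NetworkStructureError
from .network import (
    DirectedNetwork,
    WeightedNetwork,
    estimate_weighted_network,
    k_shortest_paths,
)

__all__ = [
    "EdgeModel",
    "Scenario",
    "EvaluationResult",
    "SHAPES",
    "build_benchmark_network",
    "assign_edge_models",
    "make_scenario",
    "generate_population",
    "true_top_pathways",
    "evaluate_replicates",
    "fan_network",
    "simulate_fan_data",
]

#: arcuate support half-width: phi(x) = sqrt(C - x^2) with C = ARC_C**2
ARC_C = 5.0
#: reciprocal singularity shift: phi(x) = 1 / (x + 0.5 * sign(x))
RECIP_SHIFT = 0.5


def _phi_arcuate(x):
    xc = np.clip(x, -ARC_C, ARC_C)
    return np.sqrt(ARC_C ** 2 - xc ** 2)


def _phi_reciprocal(x):
    return 1.0 / np.where(x >= 0, x + RECIP_SHIFT, x - RECIP_SHIFT)


SHAPES = {
    "linear": lambda x: x,
    "quadratic": lambda x: x ** 2,
    "cosine": np.cos,
    "sine2x": lambda x: np.sin(2.0 * x),
    "arcuate": _phi_arcuate,
    "exponential": np.exp,
    "reciprocal": _phi_reciprocal,
}

#: mixed-pattern nonlinear shape counts among the 23 effective edges,
#: keyed by nonlinear fraction: (cosine, quadratic, arcuate)
MIXED_COUNTS = {
    0.0: (0, 0, 0),
    0.3: (5, 2, 0),
    0.4: (6, 3, 0),
    0.5: (8, 4, 0),
    0.6: (8, 5, 1),
}


@dataclass
class EdgeModel:
    """Structural model for one edge: shape phi, target strength w.

    ``beta`` (coefficient on the standardised phi(parent)) and ``noise_sd``
    are derived during population generation and recorded back here.
    """

    edge: tuple[str, str]
    shape: str
    target_strength: float
    beta: float | None = None
    intercept: float | None = None
    noise_sd: float | None = None

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ConfigurationError(f"unknown edge shape '{self.shape}'")
        if not 0.0 < self.target_strength < 1.0:
            raise ConfigurationError(
                f"target strength must lie in (0, 1), got {self.target_strength}")


@dataclass
class Scenario:
    """One complete benchmark setup: network, edge models, sizes and seed."""

    network: DirectedNetwork
    effective_paths: tuple[tuple[str, ...], ...]
    edge_models: dict[tuple[str, str], EdgeModel]
    nonlinear_fraction: float
    population_size: int = 50_000
    sample_size: int = 500
    replicates: int = 500
    seed: int = 0

    @property
    def effective_edges(self) -> tuple[tuple[str, str], ...]:
        edges = set()
        for path in self.effective_paths:
            edges.update(zip(path[:-1], path[1:]))
        return tuple(sorted(edges))


@dataclass(frozen=True)
class EvaluationResult:
    """Replicate counts passing each recovery criterion for one method."""

    method: str
    sample_size: int
    replicates: int
    all_right_count: int
    range_right_count: int

    def __post_init__(self):
        if not 0 <= self.all_right_count <= self.range_right_count <= self.replicates:
            raise ValueError("criterion counts violate 0 <= all <= range <= R")


def build_benchmark_network(seed: int = 0) -> tuple[DirectedNetwork, tuple[tuple[str, ...], ...]]:
    """Seed-fixed 56-node / 82-edge DAG with 4 designated effective pathways.

    The 4 effective paths share the first edge (variant -> first expression
    node, mirroring the real-data layout) and then diverge, jointly covering
    23 distinct edges.  The remaining 35 nodes form a background chain with
    23 seeded skip edges; background edges never touch effective intermediate
    nodes, so every non-designated path carries at least two weak edges and
    the designated paths dominate by construction.
    """
    src, hub, sink = "SNP", "G00", "D"
    branches = {
        "A": 4,  # path 1: 6 edges total
        "B": 4,  # path 2: 6 edges
        "C": 5,  # path 3: 7 edges
        "E": 5,  # path 4: 7 edges
    }
    edges: list[tuple[str, str]] = [(src, hub)]
    paths = []
    for label, length in branches.items():
        chain = [f"{label}{i + 1:02d}" for i in range(length)]
        path = (src, hub, *chain, sink)
        paths.append(path)
        edges.extend(zip(path[1:-1], path[2:]))
    zs = [f"Z{i + 1:02d}" for i in range(35)]
    edges.append((src, zs[0]))
    edges.extend(zip(zs[:-1], zs[1:]))
    edges.append((zs[-1], sink))
    # 23 skip edges among {SNP} u background u {D}.  Two 3-edge variant ->
    # gene -> gene -> disease detours are always present: short weak paths
    # out-compete an effective path whose estimated strength collapses (the
    # regime the benchmark probes), yet a 3-edge product of weak strengths
    # stays below every effective path's for estimators with inflated
    # small-dependence values.  2-edge detours are excluded for the same
    # reason; the remaining 19 skips are seed-drawn.
    fixed = [(src, zs[9]), (zs[10], sink), (src, zs[19]), (zs[20], sink)]
    edges.extend(fixed)
    rng = np.random.default_rng([seed, 0])
    candidates = []
    for j in range(2, 35):
        if (src, zs[j]) not in fixed:
            candidates.append((src, zs[j]))
    for i in range(35):
        for j in range(i + 2, 35):
            candidates.append((zs[i], zs[j]))
        if i < 34 and (zs[i], sink) not in fixed:
            candidates.append((zs[i], sink))
    chosen: list[tuple[str, str]] = []
    from_src = {b for (a, b) in fixed if a == src}
    to_sink = {a for (a, b) in fixed if b == sink}
    for i in rng.permutation(len(candidates)):
        a, b = candidates[i]
        # reject a skip that would complete a 2-edge SNP -> z -> D path
        if (a == src and b in to_sink) or (b == sink and a in from_src):
            continue
        chosen.append((a, b))
        if a == src:
            from_src.add(b)
        elif b == sink:
            to_sink.add(a)
        if len(chosen) == 19:
            break
    edges.extend(sorted(chosen))
    nodes = sorted({n for e in edges for n in e})
    net = DirectedNetwork(nodes, edges, source=src, sink=sink)
    assert len(net.nodes) == 56 and len(net.edges) == 82
    return net, tuple(paths)


def assign_edge_models(net: DirectedNetwork,
                       effective_paths: tuple[tuple[str, ...], ...],
                       nonlinear_fraction: float,
                       seed: int,
                       pattern: str = "mixed",
                       population_size: int = 50_000,
                       sample_size: int = 500,
                       replicates: int = 500) -> Scenario:
    """Draw per-edge target strengths and assign structural shapes.

    Effective-path edges get w ~ U(0.75, 1), all others w ~ U(0, 0.25).
    Under the default mixed pattern the nonlinear shapes on the 23 effective
    edges are cosine/quadratic(/arcuate) in the fixed counts per fraction
    (e.g. 40% -> 6 cosine + 3 quadratic); a single-shape ``pattern`` (one of
    the nonlinear SHAPES) applies that shape to the same number of edges.
    The selected nonlinear edge subset is seed-fixed, hence identical across
    replicates.
    """
    if nonlinear_fraction not in MIXED_COUNTS:
        raise ConfigurationError(
            f"nonlinear_fraction must be one of {sorted(MIXED_COUNTS)}, "
            f"got {nonlinear_fraction}")
    eff_edges = set()
    for p in effective_paths:
        eff_edges.update(zip(p[:-1], p[1:]))
    eff_sorted = sorted(eff_edges)
    rng = np.random.default_rng([seed, 1])
    models: dict[tuple[str, str], EdgeModel] = {}
    for e in net.edges:
        lo, hi = (0.75, 1.0) if e in eff_edges else (1e-6, 0.25)
        models[e] = EdgeModel(e, "linear", float(rng.uniform(lo, hi)))
    n_cos, n_quad, n_arc = MIXED_COUNTS[nonlinear_fraction]
    n_nonlinear = n_cos + n_quad + n_arc
    if n_nonlinear:
        chosen = rng.choice(len(eff_sorted), size=n_nonlinear, replace=False)
        if pattern == "mixed":
            shapes = ["cosine"] * n_cos + ["quadratic"] * n_quad + ["arcuate"] * n_arc
        elif pattern in SHAPES and pattern != "linear":
            shapes = [pattern] * n_nonlinear
        else:
            raise ConfigurationError(f"unknown nonlinear pattern '{pattern}'")
        for idx, shape in zip(chosen, shapes):
            models[eff_sorted[idx]].shape = shape
    return Scenario(net, tuple(tuple(p) for p in effective_paths), models,
                    nonlinear_fraction, population_size, sample_size, replicates, seed)


def make_scenario(nonlinear_fraction: float = 0.0, sample_size: int = 500,
                  replicates: int = 500, seed: int = 0, pattern: str = "mixed",
                  population_size: int = 50_000) -> Scenario:
    """Convenience: benchmark network + edge models in one call."""
    net, paths = build_benchmark_network(seed)
    return assign_edge_models(net, paths, nonlinear_fraction, seed, pattern,
                              population_size, sample_size, replicates)


def _standardized(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd < 1e-12:
        raise NetworkStructureError("degenerate transformed parent (zero variance)")
    return (v - v.mean()) / sd


def generate_population(sc: Scenario) -> pd.DataFrame:
    """Generate the whole population (N rows) following the network structure.

    The source is standard normal; each child is mu + sum_p beta_p
    phi_p(parent_p) + eps in topological order.  Coefficients on the
    empirically standardised phi columns are solved from their correlation
    matrix so that corr(phi_p(parent_p), child) hits each edge's target
    strength, and every column is re-standardised to mean 0 / variance 1.
    """
    net = sc.network
    n = sc.population_size
    rng = np.random.default_rng([sc.seed, 2])
    parents: dict[str, list[tuple[str, str]]] = {v: [] for v in net.nodes}
    for (a, b) in net.edges:
        parents[b].append((a, b))
    values: dict[str, np.ndarray] = {}
    for v in net.topological_order():
        if v == net.source:
            col = rng.standard_normal(n)
            values[v] = (col - col.mean()) / col.std()
            continue
        in_edges = sorted(parents[v])
        if not in_edges:
            raise NetworkStructureError(f"non-source node '{v}' has no parents")
        phis = np.column_stack([
            _standardized(SHAPES[sc.edge_models[e].shape](values[e[0]]))
            for e in in_edges])
        w = np.array([sc.edge_models[e].target_strength for e in in_edges])
        if phis.shape[1] == 1:
            beta = w.copy()
        else:
            sigma = np.corrcoef(phis, rowvar=False)
            beta = np.linalg.solve(sigma, w)
        lin = phis @ beta
        var_lin = float(lin.var())
        if var_lin > 0.98:
            # Infeasible joint targets (several strong parents converging on
            # one child, e.g. at the sink): scale back to a positive noise
            # floor and record the proportionally reduced strengths as the
            # edges' effective targets.
            scale = np.sqrt(0.98 / var_lin)
            beta *= scale
            lin *= scale
            var_lin = 0.98
            w *= scale
            for e, wi in zip(in_edges, w):
                sc.edge_models[e].target_strength = float(wi)
        noise_sd = float(np.sqrt(1.0 - var_lin))
        col = lin + rng.normal(0.0, noise_sd, n)
        values[v] = (col - col.mean()) / col.std()
        for e, b in zip(in_edges, beta):
            m = sc.edge_models[e]
            m.beta = float(b)
            m.noise_sd = noise_sd
            m.intercept = 0.0  # nodes are standardised, so the intercept is absorbed
    return pd.DataFrame({v: values[v] for v in net.nodes})


def population_strengths(sc: Scenario, population: pd.DataFrame) -> dict[tuple[str, str], float]:
    """True per-edge strength |corr(phi(parent), child)| on the full population."""
    out = {}
    for (a, b) in sc.network.edges:
        phi = SHAPES[sc.edge_models[(a, b)].shape](population[a].to_numpy())
        child = population[b].to_numpy()
        out[(a, b)] = abs(float(np.corrcoef(phi, child)[0, 1]))
    return out


def true_top_pathways(sc: Scenario, population: pd.DataFrame,
                      k: int = 4) -> list[tuple[str, ...]]:
    """The k largest-effect source->sink chains under the population strengths."""
    w = WeightedNetwork.from_strengths(sc.network, population_strengths(sc, population))
    return [p.nodes for p in k_shortest_paths(w, k)]


def evaluate_replicates(sc: Scenario, population: pd.DataFrame,
                        method: DependenceMethod | str, cfg=None,
                        truth: list[tuple[str, ...]] | None = None,
                        replicates: int | None = None) -> EvaluationResult:
    """Score R subsample replicates for one method under both criteria.

    Each replicate draws ``sc.sample_size`` of the N population rows without
    replacement (an independent, seed-derived substream per replicate),
    re-estimates all 82 edge strengths with ``method``, runs the 4-shortest-
    paths search, and is scored all-right (exact ordered match with the true
    top 4) and range-right (set match).  Estimator failures count as misses
    for both criteria, so denominators always equal R.
    """
    method = DependenceMethod(method)
    if truth is None:
        truth = true_top_pathways(sc, population)
    truth_set = set(truth)
    k = len(truth)
    r = sc.replicates if replicates is None else replicates
    n_pop = population.shape[0]
    cols = {v: population[v].to_numpy() for v in sc.network.nodes}
    all_right = 0
    range_right = 0
    for i in range(r):
        rng = np.random.default_rng([sc.seed, 3, i])
        idx = rng.choice(n_pop, size=sc.sample_size, replace=False)
        sub = {v: cols[v][idx] for v in cols}
        try:
            w = estimate_weighted_network(sub, sc.network, method, cfg)
            pred = [p.nodes for p in k_shortest_paths(w, k)]
        except Exception:  # degenerate subsample column etc. -> scored as a miss
            continue
        if len(pred) == k and set(pred) == truth_set:
            range_right += 1
            if pred == list(truth):
                all_right += 1
    return EvaluationResult(method.value, sc.sample_size, r, all_right, range_right)


def fan_network() -> DirectedNetwork:
    """The 6-pathway fan used in examples and tests.

    Mirrors the structure of the real APOE -> AD network's six named chains:
    genotype -> APOE expression -> {GRIN2A, CACNA1C} -> {CAPN2 -> MAPT,
    MAPK1 -> CASP3, NOS1} -> AD (2 x 3 = 6 source->sink paths).
    """
    edges = [
        ("APOEg", "APOEe"),
        ("APOEe", "GRIN2A"), ("APOEe", "CACNA1C"),
        ("GRIN2A", "CAPN2"), ("GRIN2A", "MAPK1"), ("GRIN2A", "NOS1"),
        ("CACNA1C", "CAPN2"), ("CACNA1C", "MAPK1"), ("CACNA1C", "NOS1"),
        ("CAPN2", "MAPT"), ("MAPK1", "CASP3"),
        ("MAPT", "AD"), ("CASP3", "AD"), ("NOS1", "AD"),
    ]
    nodes = sorted({n for e in edges for n in e})
    return DirectedNetwork(nodes, edges, source="APOEg", sink="AD")


DEFAULT_FAN_STRENGTHS = {
    ("APOEg", "APOEe"): 0.55,
    ("APOEe", "GRIN2A"): 0.85, ("APOEe", "CACNA1C"): 0.60,
    ("GRIN2A", "CAPN2"): 0.80, ("GRIN2A", "MAPK1"): 0.45, ("GRIN2A", "NOS1"): 0.70,
    ("CACNA1C", "CAPN2"): 0.55, ("CACNA1C", "MAPK1"): 0.40, ("CACNA1C", "NOS1"): 0.50,
    ("CAPN2", "MAPT"): 0.85, ("MAPK1", "CASP3"): 0.75,
    ("MAPT", "AD"): 0.70, ("CASP3", "AD"): 0.55, ("NOS1", "AD"): 0.65,
}


def simulate_fan_data(n: int = 400, seed: int = 0,
                      strengths: dict[tuple[str, str], float] | None = None) -> pd.DataFrame:
    """Synthetic samples for the fan network: binary genotype and disease,
    standardised continuous expression nodes, linear edges with the given
    target strengths (disease is a thresholded liability, which attenuates
    the sink-edge correlations but preserves their ordering)."""
    net = fan_network()
    strengths = dict(DEFAULT_FAN_STRENGTHS if strengths is None else strengths)
    rng = np.random.default_rng([seed, 7])
    parents: dict[str, list[str]] = {v: [] for v in net.nodes}
    for (a, b) in net.edges:
        parents[b].append(a)
    values: dict[str, np.ndarray] = {}
    for v in net.topological_order():
        if v == net.source:
            values[v] = rng.binomial(1, 0.5, n).astype(float)
            continue
        phis = np.column_stack([
            _standardized(values[p]) for p in sorted(parents[v])])
        w = np.array([strengths[(p, v)] for p in sorted(parents[v])])
        if phis.shape[1] > 1:
            w = np.linalg.solve(np.corrcoef(phis, rowvar=False), w)
        lin = phis @ w
        var_lin = min(float(lin.var()), 0.98)
        col = lin + rng.normal(0.0, np.sqrt(1.0 - var_lin), n)
        if v == net.sink:
            values[v] = (col > np.median(col)).astype(float)
        else:
            values[v] = (col - col.mean()) / col.std()
    return pd.DataFrame({v: values[v] for v in net.nodes})
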