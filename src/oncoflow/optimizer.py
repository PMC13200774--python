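"""Adoption-path optimization over the strategy grid.

The sweep grid becomes a weighted directed acyclic graph whose edges are
orthogonal monotone moves (one grid step in A or in I, never both).  Each
node carries a composite cost — the equally weighted sum of four grid
min-max-normalized components: mean RTTI, RTTI SD, reciprocal throughput,
and throughput SD.  Edge weight is the cost of the state being entered, so
a path's total cost is the cumulative operational friction of the adoption
sequence, excluding the unavoidable starting state.  Dijkstra (networkx)
finds the minimum-cost monotone path from (0,0) to (1,1), benchmarked
against the two corner strategies (automation first / interoperability
first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx

from .config import CostWeights
from .metrics import combined_volatility
from .sweep import SweepResult, grid_coordinates

Coordinate = Tuple[float, float]


@dataclass
class TransitionGraph:
    """Weighted DAG over the grid with per-node composite costs."""

    resolution: int
    graph: nx.DiGraph
    node_costs: Dict[Coordinate, float]


@dataclass
class StrategyPath:
    """An ordered monotone adoption sequence from (0,0) to (1,1)."""

    nodes: List[Coordinate]
    total_cost: float
    profile: List[dict] = field(default_factory=list)


def minmax_normalize(values: List[float]) -> List[float]:
    """Min-max normalization to [0, 1]; constant input maps to all zeros."""
    if not values:
        raise ValueError("empty input")
    lo, hi = min(values), max(values)
    if hi == lo:
        return [0.0] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def node_cost(normalized_components: Tuple[float, float, float, float],
              weights: CostWeights) -> float:
    """Weighted sum of the four normalized cost components."""
    n_rtti, n_rtti_sd, n_thr_inv, n_thr_sd = normalized_components
    return (weights.w_rtti_mean * n_rtti
            + weights.w_rtti_sd * n_rtti_sd
            + weights.w_thr_inv * n_thr_inv
            + weights.w_thr_sd * n_thr_sd)


def _grid_node_costs(sweep: SweepResult, weights: CostWeights,
                     throughput_inverse: str = "reciprocal"
                     ) -> Dict[Coordinate, float]:
    weights.validate()
    coords = sweep.coordinates
    aggs = sweep.aggregates
    if set(aggs) != set(coords):
        raise ValueError("incomplete sweep")
    rtti = [aggs[c].mean_rtti for c in coords]
    rtti_sd = [aggs[c].sd_rtti for c in coords]
    thr = [aggs[c].mean_throughput for c in coords]
    thr_sd = [aggs[c].sd_throughput for c in coords]
    if throughput_inverse == "reciprocal":
        grid_max_thr = max(thr)
        # zero throughput has undefined reciprocal: flag with the grid max
        thr_inv = [1.0 / t if t > 0 else float("inf") for t in thr]
        finite = [t for t in thr_inv if t != float("inf")]
        cap = max(finite) if finite else 1.0
        thr_inv = [cap if t == float("inf") else t for t in thr_inv]
    elif throughput_inverse == "one_minus_normalized":
        thr_inv = [-t for t in thr]  # normalizes to 1 - n(throughput)
    else:
        raise ValueError(f"unknown throughput_inverse '{throughput_inverse}'")
    n1 = minmax_normalize(rtti)
    n2 = minmax_normalize(rtti_sd)
    n3 = minmax_normalize(thr_inv)
    n4 = minmax_normalize(thr_sd)
    return {
        c: node_cost((n1[i], n2[i], n3[i], n4[i]), weights)
        for i, c in enumerate(coords)
    }


def build_graph(sweep: SweepResult, weights: Optional[CostWeights] = None,
                throughput_inverse: str = "reciprocal") -> TransitionGraph:
    """Build the monotone-move transition graph over the sweep grid.

    Edge (u -> v) exists iff v increases exactly one axis by one grid step;
    its weight is the composite cost of v (cost accrues on entering a
    state).
    """
    weights = weights or CostWeights()
    costs = _grid_node_costs(sweep, weights, throughput_inverse)
    return build_graph_from_costs(sweep.resolution, costs)


def build_graph_from_costs(resolution: int,
                           costs: Dict[Coordinate, float]) -> TransitionGraph:
    """Assemble the lattice DAG from explicit per-node costs."""
    coords = grid_coordinates(resolution)
    missing = set(coords) - set(costs)
    if missing:
        raise ValueError(f"costs missing for {len(missing)} grid nodes")
    axis = sorted({c[0] for c in coords})
    g = nx.DiGraph()
    g.add_nodes_from(coords)
    n = len(axis)
    for ai, a in enumerate(axis):
        for ii, i in enumerate(axis):
            if ai + 1 < n:
                v = (axis[ai + 1], i)
                g.add_edge((a, i), v, weight=costs[v])
            if ii + 1 < n:
                v = (a, axis[ii + 1])
                g.add_edge((a, i), v, weight=costs[v])
    return TransitionGraph(resolution=resolution, graph=g, node_costs=costs)


def optimal_path(tgraph: TransitionGraph) -> StrategyPath:
    """Minimum cumulative-cost monotone path from (0,0) to (1,1) (Dijkstra).

    Ties between equal-cost paths are broken deterministically in favor of
    the lexicographically smallest node sequence.
    """
    source, target = (0.0, 0.0), (1.0, 1.0)
    g = tgraph.graph
    # lexicographic tie-break: augment the cost with a tuple-valued
    # secondary criterion resolved by explicit dynamic programming over the
    # DAG (grid processed in topological = anti-diagonal order)
    dist: Dict[Coordinate, float] = {source: 0.0}
    best_seq: Dict[Coordinate, tuple] = {source: (source,)}
    order = sorted(g.nodes, key=lambda c: (c[0] + c[1], c))
    for node in order:
        if node not in dist:
            continue
        for _, v, data in g.out_edges(node, data=True):
            cand = dist[node] + data["weight"]
            seq = best_seq[node] + (v,)
            if (v not in dist or cand < dist[v] - 1e-15
                    or (abs(cand - dist[v]) <= 1e-15 and seq < best_seq[v])):
                dist[v] = cand
                best_seq[v] = seq
    if target not in dist:
        raise ValueError("target unreachable")
    # cross-check with networkx Dijkstra (same total cost, by construction)
    nx_cost = nx.dijkstra_path_length(g, source, target)
    assert abs(nx_cost - dist[target]) < 1e-9
    return StrategyPath(nodes=list(best_seq[target]), total_cost=dist[target])


def path_cost(tgraph: TransitionGraph, nodes: List[Coordinate]) -> float:
    """Cumulative cost of an explicit path (entering-state accounting)."""
    return sum(tgraph.node_costs[n] for n in nodes[1:])


def corner_path(kind: str, resolution: int) -> StrategyPath:
    """A corner benchmark strategy: maximize one lever fully, then the other."""
    step = 1.0 / (resolution - 1)
    nodes: List[Coordinate] = []
    if kind == "automation_first":
        nodes += [(round(k * step, 10), 0.0) for k in range(resolution)]
        nodes += [(1.0, round(k * step, 10)) for k in range(1, resolution)]
    elif kind == "interoperability_first":
        nodes += [(0.0, round(k * step, 10)) for k in range(resolution)]
        nodes += [(round(k * step, 10), 1.0) for k in range(1, resolution)]
    else:
        raise ValueError(f"unknown corner strategy '{kind}'")
    return StrategyPath(nodes=nodes, total_cost=float("nan"))


def path_profile(path: StrategyPath, sweep: SweepResult) -> List[dict]:
    """Per-node normalized profile along a path.

    efficiency = 1 - n(mean RTTI), throughput = n(throughput),
    stability = 1 - n(volatility); progress runs 0 -> 1 along the path.
    All normalizations are over the full sweep grid.
    """
    coords = sweep.coordinates
    aggs = sweep.aggregates
    missing = [n for n in path.nodes if n not in aggs]
    if missing:
        raise ValueError(f"path nodes missing from sweep: {missing}")
    n_rtti = dict(zip(coords,
                      minmax_normalize([aggs[c].mean_rtti for c in coords])))
    n_thr = dict(zip(coords,
                     minmax_normalize([aggs[c].mean_throughput
                                       for c in coords])))
    vol = combined_volatility(aggs)
    n_vol = dict(zip(list(vol), minmax_normalize(list(vol.values()))))
    K = len(path.nodes)
    profile = []
    for k, node in enumerate(path.nodes):
        profile.append({
            "node": node,
            "progress": k / (K - 1) if K > 1 else 0.0,
            "efficiency": 1.0 - n_rtti[node],
            "throughput": n_thr[node],
            "stability": 1.0 - n_vol[node],
        })
    path.profile = profile
    return profile
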