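"""Transition-graph optimization: normalization, costs, Dijkstra, paths."""

import itertools
import random

import pytest

from oncoflow import (
    build_graph,
    corner_path,
    minmax_normalize,
    node_cost,
    optimal_path,
    path_profile,
)
from oncoflow.config import CostWeights
from oncoflow.metrics import AggregateMetrics
from oncoflow.optimizer import build_graph_from_costs, path_cost
from oncoflow.sweep import SweepResult, grid_coordinates


def enumerate_monotone_paths(resolution):
    """All C(2(n-1), n-1) monotone lattice paths from (0,0) to (1,1)."""
    n = resolution - 1
    step = 1.0 / n
    for pattern in itertools.combinations(range(2 * n), n):
        a = i = 0
        nodes = [(0.0, 0.0)]
        for k in range(2 * n):
            if k in pattern:
                a += 1
            else:
                i += 1
            nodes.append((round(a * step, 10), round(i * step, 10)))
        yield nodes


def random_cost_sweep(resolution, rng):
    """A SweepResult with random aggregate surfaces."""
    coords = grid_coordinates(resolution)
    aggregates = {
        c: AggregateMetrics(
            n_replications=2,
            mean_rtti=rng.uniform(10, 40), sd_rtti=rng.uniform(0, 3),
            mean_throughput=rng.uniform(500, 1300),
            sd_throughput=rng.uniform(0, 30),
            mean_governance_density=0, sd_governance_density=0,
            mean_fp_rate=0, sd_fp_rate=0, mean_utilization={},
            modal_bottleneck="x", modal_bottleneck_count=2)
        for c in coords
    }
    return SweepResult(resolution=resolution, replications=2, base_seed=0,
                       coordinates=coords, aggregates=aggregates)


class TestMinmaxNormalize:
    def test_basic(self):
        assert minmax_normalize([10, 20, 30]) == [0.0, 0.5, 1.0]

    def test_constant_input_maps_to_zeros(self):
        assert minmax_normalize([5, 5, 5]) == [0.0, 0.0, 0.0]

    def test_range_is_unit_for_nonconstant(self):
        out = minmax_normalize([3.2, -1.0, 7.7, 2.2])
        assert min(out) == 0.0 and max(out) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize([])


class TestNodeCost:
    def test_all_minimum_components_cost_zero(self):
        assert node_cost((0, 0, 0, 0), CostWeights()) == 0.0

    def test_all_maximum_components_cost_one(self):
        assert node_cost((1, 1, 1, 1), CostWeights()) == pytest.approx(1.0)

    def test_equal_weights_arithmetic(self):
        assert node_cost((0.2, 0.4, 0.6, 0.8), CostWeights()) == \
            pytest.approx(0.5)


class TestBuildGraph:
    def test_node_and_edge_counts_11(self):
        rng = random.Random(0)
        tg = build_graph(random_cost_sweep(11, rng))
        assert tg.graph.number_of_nodes() == 121
        assert tg.graph.number_of_edges() == 220   # 2 * 11 * 10

    def test_terminal_has_no_outgoing_edges(self):
        tg = build_graph(random_cost_sweep(4, random.Random(1)))
        assert tg.graph.out_degree((1.0, 1.0)) == 0
        assert tg.graph.out_degree((0.0, 0.0)) == 2

    def test_costs_lie_in_unit_interval(self):
        tg = build_graph(random_cost_sweep(5, random.Random(2)))
        assert all(0.0 <= c <= 1.0 + 1e-12 for c in tg.node_costs.values())


class TestOptimalPath:
    def test_two_by_two_hand_check(self):
        # enter-state costs: via (0,1) costs 0.3+0.2, via (1,0) costs 0.9+0.2
        costs = {(0.0, 0.0): 0.4, (0.0, 1.0): 0.3,
                 (1.0, 0.0): 0.9, (1.0, 1.0): 0.2}
        tg = build_graph_from_costs(2, costs)
        path = optimal_path(tg)
        assert path.nodes == [(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)]
        assert path.total_cost == pytest.approx(0.5)

    def test_equal_costs_tie_breaks_lexicographically(self):
        costs = {c: 1.0 for c in grid_coordinates(3)}
        path = optimal_path(build_graph_from_costs(3, costs))
        # lexicographically smallest: all I-moves first
        assert path.nodes == [(0.0, 0.0), (0.0, 0.5), (0.0, 1.0),
                              (0.5, 1.0), (1.0, 1.0)]

    @pytest.mark.parametrize("resolution", [3, 4, 6])
    def test_matches_exhaustive_enumeration(self, resolution):
        rng = random.Random(123 + resolution)
        for _ in range(10):
            sweep = random_cost_sweep(resolution, rng)
            tg = build_graph(sweep)
            best = optimal_path(tg)
            brute = min(sum(tg.node_costs[n] for n in nodes[1:])
                        for nodes in enumerate_monotone_paths(resolution))
            assert best.total_cost == pytest.approx(brute, abs=1e-12)

    def test_shift_invariance_of_argmin(self):
        rng = random.Random(9)
        sweep = random_cost_sweep(5, rng)
        tg = build_graph(sweep)
        shifted = build_graph_from_costs(
            5, {c: v + 0.7 for c, v in tg.node_costs.items()})
        assert optimal_path(tg).nodes == optimal_path(shifted).nodes

    def test_monotone_coordinates_along_path(self):
        tg = build_graph(random_cost_sweep(6, random.Random(3)))
        nodes = optimal_path(tg).nodes
        assert all(b[0] >= a[0] and b[1] >= a[1]
                   for a, b in zip(nodes, nodes[1:]))
        assert len(nodes) == 2 * 5 + 1

    def test_optimal_never_beaten_by_corner_strategies(self):
        for seed in range(5):
            tg = build_graph(random_cost_sweep(5, random.Random(seed)))
            best = optimal_path(tg).total_cost
            for kind in ("automation_first", "interoperability_first"):
                assert best <= path_cost(tg, corner_path(kind, 5).nodes) + 1e-12


class TestCornerPaths:
    def test_automation_first_shape(self):
        path = corner_path("automation_first", 11)
        assert len(path.nodes) == 21
        assert path.nodes[10] == (1.0, 0.0)
        assert path.nodes[-1] == (1.0, 1.0)

    def test_interoperability_first_shape(self):
        path = corner_path("interoperability_first", 11)
        assert path.nodes[10] == (0.0, 1.0)

    def test_edge_count(self):
        for kind in ("automation_first", "interoperability_first"):
            assert len(corner_path(kind, 11).nodes) - 1 == 20

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            corner_path("diagonal", 11)


class TestPathProfile:
    def test_progress_endpoints_and_ranges(self):
        sweep = random_cost_sweep(5, random.Random(4))
        tg = build_graph(sweep)
        path = optimal_path(tg)
        profile = path_profile(path, sweep)
        assert profile[0]["progress"] == 0.0
        assert profile[-1]["progress"] == 1.0
        for row in profile:
            for key in ("efficiency", "throughput", "stability"):
                assert 0.0 <= row[key] <= 1.0

    def test_grid_max_rtti_has_zero_efficiency(self):
        sweep = random_cost_sweep(3, random.Random(5))
        worst = max(sweep.coordinates,
                    key=lambda c: sweep.aggregates[c].mean_rtti)
        path = corner_path("automation_first", 3)
        if worst in path.nodes:
            profile = path_profile(path, sweep)
            row = next(r for r in profile if r["node"] == worst)
            assert row["efficiency"] == 0.0

    def test_missing_node_rejected(self):
        sweep = random_cost_sweep(3, random.Random(6))
        path = corner_path("automation_first", 5)  # finer grid than sweep
        with pytest.raises(ValueError):
            path_profile(path, sweep)
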