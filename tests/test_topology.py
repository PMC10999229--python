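"""Betti-0 filtration: cutoff weights, union-find component counts against a
graph-traversal oracle, curve shape, and trapezoidal AUC."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import topoconn as tc
from topoconn.errors import (
    DegenerateCurveError,
    InvalidParameterError,
)
from topoconn.topology import BettiCurve

from conftest import random_matrix


def bfs_component_count(m: tc.ConnectivityMatrix, density: float) -> int:
    """Independent oracle: component count of the top-ranked edge set via
    networkx traversal (same rank rule, different machinery)."""
    n = m.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = m.weights[iu, ju]
    order = np.lexsort((ju, iu, -w))
    k = min(len(w), math.ceil(density * len(w)))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(iu[order[:k]], ju[order[:k]]))
    return nx.number_connected_components(g)


def two_triangle_bridge():
    """Two triangles (strong edges) joined by one weak bridge; all other
    pairs weaker still."""
    w = np.full((6, 6), 0.1)
    tri = [(0, 1, 0.95), (0, 2, 0.9), (1, 2, 0.85), (3, 4, 0.8), (3, 5, 0.75), (4, 5, 0.7)]
    for i, j, v in tri:
        w[i, j] = w[j, i] = v
    w[2, 3] = w[3, 2] = 0.5  # the bridge: rank 7 of 15
    np.fill_diagonal(w, 0.0)
    return tc.ConnectivityMatrix(tuple(range(6)), w)


class TestCutoffWeight:
    def test_density_one_is_minimum_weight(self):
        m = random_matrix(np.random.default_rng(0), 10)
        assert tc.cutoff_weight(m, 1.0) == pytest.approx(m.pair_weights().min())

    def test_rank_two_is_second_largest(self):
        w = np.zeros((4, 4))
        vals = iter([0.9, 0.7, 0.5, 0.3, 0.2, 0.1])
        for i in range(4):
            for j in range(i + 1, 4):
                w[i, j] = w[j, i] = next(vals)
        m = tc.ConnectivityMatrix(tuple(range(4)), w)
        # ceil(0.3 * 6) = 2 -> second-largest weight
        assert tc.cutoff_weight(m, 0.3) == pytest.approx(0.7)

    def test_density_zero_sentinel(self):
        m = random_matrix(np.random.default_rng(1), 5)
        assert tc.cutoff_weight(m, 0.0) == math.inf

    def test_out_of_range_density(self):
        m = random_matrix(np.random.default_rng(2), 5)
        with pytest.raises(InvalidParameterError):
            tc.cutoff_weight(m, 1.5)


class TestBetti0At:
    def test_all_nodes_isolated_at_zero(self):
        m = random_matrix(np.random.default_rng(3), 17)
        assert tc.betti0_at(m, 0.0) == 17

    def test_spanning_density_gives_one(self):
        m = random_matrix(np.random.default_rng(4), 12)
        assert tc.betti0_at(m, 1.0) == 1

    def test_matches_traversal_oracle_spot_checks(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(20, 41))
            m = random_matrix(rng, n)
            d = float(rng.uniform(0, 0.3))
            assert tc.betti0_at(m, d) == bfs_component_count(m, d)


class TestBettiCurve:
    def test_immediate_merge_two_points(self):
        # a 5-node chain of 4 huge edges within the top 1% is impossible at
        # E=10 edges; build n large enough that ceil(0.01*E) covers a
        # spanning tree: n=30, E=435, ceil=5 edges < 29 needed, so instead
        # plant a star whose edges are the top ceil(0.01*E) ranks at n=15
        n = 15
        w = np.full((n, n), -0.5)
        rng = np.random.default_rng(6)
        w += rng.normal(0, 0.01, (n, n))
        w = (w + w.T) / 2
        for j in range(1, n):
            w[0, j] = w[j, 0] = 5.0 + j  # star spans all nodes, top ranks
        np.fill_diagonal(w, 0)
        m = tc.ConnectivityMatrix(tuple(range(n)), w)
        # ceil(0.14 * 105) = 15 >= 14 star edges -> connected at one step
        curve = tc.betti0_curve(m, step=0.14)
        assert list(curve.b0_values) == [n, 1]
        assert list(curve.thresholds) == [0.0, 0.14]

    def test_bridge_plateau(self):
        m = two_triangle_bridge()
        curve = tc.betti0_curve(m, step=0.01)
        assert curve.b0_values[0] == 6
        assert curve.b0_values[-1] == 1
        # plateau at 2 components persists until the bridge (rank 7) enters
        plateau = curve.b0_values[
            (curve.thresholds >= 6 / 15) & (curve.thresholds < 0.41)
        ]
        assert np.all(plateau == 2)
        first_one = curve.thresholds[np.argmax(curve.b0_values == 1)]
        assert first_one == pytest.approx(0.41)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_curve_non_increasing_and_terminates(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, int(rng.integers(10, 30)))
        curve = tc.betti0_curve(m)
        assert curve.b0_values[0] == m.n_nodes
        assert curve.b0_values[-1] == 1
        assert np.all(np.diff(curve.b0_values) <= 0)
        assert not curve.truncated

    def test_rank_invariance_fisher_z_vs_r(self):
        """Density-mode curves depend on edge ranks only, so the monotone
        Fisher transform leaves them unchanged."""
        rng = np.random.default_rng(8)
        r = np.clip(rng.normal(0.1, 0.3, (20, 20)), -0.99, 0.99)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        m_r = tc.ConnectivityMatrix(tuple(range(20)), r)
        m_z = tc.ConnectivityMatrix(tuple(range(20)), np.arctanh(r))
        c_r, c_z = tc.betti0_curve(m_r), tc.betti0_curve(m_z)
        np.testing.assert_array_equal(c_r.b0_values, c_z.b0_values)
        assert tc.auc(c_r) == pytest.approx(tc.auc(c_z))

    def test_constant_shift_invariance_density_mode(self):
        m = random_matrix(np.random.default_rng(9), 15)
        shifted = tc.ConnectivityMatrix(m.node_ids, m.weights + 0.7)
        c1, c2 = tc.betti0_curve(m), tc.betti0_curve(shifted)
        np.testing.assert_array_equal(c1.b0_values, c2.b0_values)

    def test_correlation_mode_shifts_under_constant(self):
        rng = np.random.default_rng(10)
        r = np.clip(rng.normal(0.0, 0.2, (12, 12)), -0.8, 0.8)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        m = tc.ConnectivityMatrix(tuple(range(12)), np.arctanh(r))
        shifted = tc.ConnectivityMatrix(
            tuple(range(12)), np.arctanh(np.clip(r + 0.15, -0.99, 0.99))
        )
        c1 = tc.betti0_curve(m, mode="correlation")
        c2 = tc.betti0_curve(shifted, mode="correlation")
        assert c1.mode == "correlation"
        assert c1.b0_values[-1] == 1
        assert tc.auc(c1) != pytest.approx(tc.auc(c2))

    def test_raising_an_edge_cannot_increase_auc(self):
        m = two_triangle_bridge()
        base = tc.auc(tc.betti0_curve(m))
        w = m.weights.copy()
        w[2, 3] = w[3, 2] = 0.97  # bridge promoted to near-top rank
        perturbed = tc.ConnectivityMatrix(m.node_ids, w)
        assert tc.auc(tc.betti0_curve(perturbed)) <= base

    def test_invalid_step(self):
        m = random_matrix(np.random.default_rng(11), 6)
        with pytest.raises(InvalidParameterError):
            tc.betti0_curve(m, step=0.0)


class TestAuc:
    def test_three_point_trapezoid(self):
        curve = BettiCurve(
            "density", [0.0, 0.01, 0.02], [np.inf, 1.0, 0.5], [5, 3, 1], 5
        )
        assert tc.auc(curve) == pytest.approx(0.06)

    def test_two_point_single_trapezoid(self):
        n = 264
        curve = BettiCurve("density", [0.0, 0.01], [np.inf, 1.0], [n, 1], n)
        assert tc.auc(curve) == pytest.approx(0.01 * (n + 1) / 2)

    def test_constant_plateau_rectangle(self):
        curve = BettiCurve(
            "density", [0.0, 0.1, 0.2, 0.3], [np.inf, 3, 2, 1], [4, 4, 4, 1], 4
        )
        # integrates plateau 4 over width 0.2 plus final trapezoid
        assert tc.auc(curve) == pytest.approx(4 * 0.2 + 0.1 * (4 + 1) / 2)

    def test_integration_stops_at_first_unity(self):
        curve = BettiCurve(
            "density", [0.0, 0.1, 0.2, 0.3], [np.inf, 3, 2, 1], [3, 1, 1, 1], 3
        )
        assert tc.auc(curve) == pytest.approx(0.1 * (3 + 1) / 2)

    def test_degenerate_curve(self):
        with pytest.raises(DegenerateCurveError):
            tc.auc(BettiCurve("density", [0.0], [np.inf], [1], 1))


def test_higher_within_coupling_raises_mean_auc():
    """Stronger community coupling delays global merging: mean AUC over seeds
    increases with the within-community loading (sign-only)."""
    part = tc.simulate_partition(40, 5)
    means = []
    for a in (0.45, 0.9):
        cfg = tc.SimulationConfig(
            n_nodes=40, n_networks=5, series_length=150, domains=("fluid",),
            within_coupling=a, between_coupling=0.3,
        )
        vals = [
            tc.auc(
                tc.betti0_curve(
                    tc.correlation_matrix(
                        tc.simulate_timeseries(part, cfg, "bl", 50.0, seed=s)
                    )
                )
            )
            for s in range(12)
        ]
        means.append(np.mean(vals))
    assert means[1] > means[0]
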