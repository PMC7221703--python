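"""Random walk with restart: transition matrix, convergence, and oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbnet import (
    ConvergenceError,
    LayeredGraph,
    LayerTag,
    ValidationError,
    normalize_adjacency,
    phenotype_scores,
    rwr,
    rwr_closed_form,
)


def two_node_graph():
    g = LayeredGraph()
    t = g.add_node(LayerTag.TARGET, "T1")
    p = g.add_node(LayerTag.PATHWAY, "P1")
    g.add_edge(t, p)
    return g


def path3_graph():
    """a - b - c path: PATHWAY:P1 - TARGET:T1 - PHENOTYPE:phen."""
    g = LayeredGraph()
    t = g.add_node(LayerTag.TARGET, "T1")
    p = g.add_node(LayerTag.PATHWAY, "P1")
    ph = g.add_node(LayerTag.PHENOTYPE, "phen")
    g.add_edge(t, p)
    g.add_edge(t, ph)
    return g


def random_transition(rng, n):
    """Row-stochastic symmetric-connectivity matrix of a random graph."""
    g = LayeredGraph()
    tgts = [g.add_node(LayerTag.TARGET, f"T{i}") for i in range(n)]
    pws = [g.add_node(LayerTag.PATHWAY, f"P{i}") for i in range(n)]
    for t in tgts:
        for p in pws:
            if rng.random() < 0.4:
                g.add_edge(t, p)
    return normalize_adjacency(g)


class TestNormalizeAdjacency:
    def test_single_edge_swaps_mass(self):
        tm = normalize_adjacency(two_node_graph())
        assert np.array_equal(tm.matrix, [[0, 1], [1, 0]])

    def test_isolated_node_gets_self_loop(self):
        g = LayeredGraph()
        g.add_node(LayerTag.TARGET, "T1")
        tm = normalize_adjacency(g)
        assert np.array_equal(tm.matrix, [[1.0]])

    def test_path_center_splits_evenly(self):
        tm = normalize_adjacency(path3_graph())
        row = tm.matrix[tm.index["TARGET:T1"]]
        others = [tm.index["PATHWAY:P1"], tm.index["PHENOTYPE:phen"]]
        assert row[tm.index["TARGET:T1"]] == 0
        assert all(row[i] == 0.5 for i in others)

    def test_rows_sum_to_one(self, fixture_data):
        g, _ = fixture_data
        tm = normalize_adjacency(g)
        assert np.allclose(tm.matrix.sum(axis=1), 1.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            normalize_adjacency(LayeredGraph())


class TestRWR:
    def test_alpha_zero_returns_restart_vector(self):
        tm = normalize_adjacency(two_node_graph())
        f0 = np.array([1.0, 0.0])
        res = rwr(tm, f0, alpha=0.0)
        assert res.iterations == 1
        assert np.array_equal(res.scores, f0)

    def test_symmetric_graph_uniform_start_stays_uniform(self):
        tm = normalize_adjacency(two_node_graph())
        res = rwr(tm, np.array([0.5, 0.5]), alpha=0.7)
        assert np.allclose(res.scores, [0.5, 0.5])

    def test_path3_matches_closed_form(self):
        tm = normalize_adjacency(path3_graph())
        f0 = np.zeros(3)
        f0[tm.index["PATHWAY:P1"]] = 1.0
        res = rwr(tm, f0, alpha=0.5, threshold=1e-12)
        exact = rwr_closed_form(tm, f0, alpha=0.5)
        assert np.allclose(res.scores, exact, atol=1e-8)

    def test_mass_conserved_along_iteration(self):
        rng = np.random.default_rng(0)
        tm = random_transition(rng, 5)
        f = np.zeros(tm.n)
        f[0] = 1.0
        f0 = f.copy()
        for _ in range(50):
            f = 0.7 * (f @ tm.matrix) + 0.3 * f0
            assert np.isclose(f.sum(), 1.0)
            assert f.min() >= 0

    def test_residual_decays_geometrically(self):
        rng = np.random.default_rng(1)
        tm = random_transition(rng, 6)
        f0 = np.zeros(tm.n)
        f0[0] = 1.0
        alpha, f, prev = 0.8, f0.copy(), None
        for t in range(1, 30):
            f_next = alpha * (f @ tm.matrix) + (1 - alpha) * f0
            residual = np.abs(f_next - f).sum()
            assert residual <= 2 * alpha**t + 1e-12
            f = f_next

    def test_nonconvergence_error_carries_residual(self):
        tm = normalize_adjacency(two_node_graph())
        with pytest.raises(ConvergenceError) as exc:
            rwr(tm, np.array([1.0, 0.0]), alpha=0.9, threshold=1e-12, max_iter=2)
        assert exc.value.residual > 0 and exc.value.iterations == 2

    def test_invalid_alpha_rejected(self):
        tm = normalize_adjacency(two_node_graph())
        with pytest.raises(ValidationError):
            rwr(tm, np.array([1.0, 0.0]), alpha=1.0)


class TestClosedForm:
    def test_alpha_zero_is_restart_vector(self):
        tm = normalize_adjacency(two_node_graph())
        f0 = np.array([0.25, 0.75])
        assert np.array_equal(rwr_closed_form(tm, f0, alpha=0.0), f0)

    def test_identity_matrix_fixed_point_is_f0(self):
        g = LayeredGraph()
        g.add_node(LayerTag.TARGET, "T1")
        g.add_node(LayerTag.TARGET, "T2")
        tm = normalize_adjacency(g)  # two self-loops = identity
        f0 = np.array([0.3, 0.7])
        assert np.allclose(rwr_closed_form(tm, f0, alpha=0.6), f0)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), alpha=st.floats(0.05, 0.95))
    def test_iterative_agrees_with_linear_solve(self, seed, alpha):
        """Fixed point of the iteration equals the direct solve."""
        rng = np.random.default_rng(seed)
        tm = random_transition(rng, int(rng.integers(2, 8)))
        f0 = rng.random(tm.n)
        f0 /= f0.sum()
        threshold = 1e-10
        res = rwr(tm, f0, alpha=alpha, threshold=threshold, max_iter=10_000)
        exact = rwr_closed_form(tm, f0, alpha=alpha)
        assert np.abs(res.scores - exact).sum() <= 10 * threshold


class TestPhenotypeScores:
    def test_unreachable_phenotype_scores_zero(self):
        g = LayeredGraph()
        c = g.add_node(LayerTag.COMPONENT, "c1")
        t = g.add_node(LayerTag.TARGET, "T1")
        g.add_edge(c, t)
        g.add_node(LayerTag.PHENOTYPE, "far away")  # isolated
        scores = phenotype_scores(g, ["TARGET:T1"])
        assert scores["PHENOTYPE:far away"].raw == pytest.approx(0.0, abs=1e-9)

    def test_empty_start_set_rejected(self, fixture_data):
        g, _ = fixture_data
        with pytest.raises(ValidationError):
            phenotype_scores(g, [])

    def test_degree_proportional_start_recovers_baseline(self, fixture_data):
        """Starting from the topology baseline, normalized scores are 1."""
        from herbnet.randomwalk import degree_restart, normalize_adjacency, rwr

        g, _ = fixture_data
        tm = normalize_adjacency(g)
        f0 = degree_restart(tm, g)
        res = rwr(tm, f0, alpha=0.7, threshold=1e-12)
        exact = rwr_closed_form(tm, f0, alpha=0.7)
        assert np.allclose(res.scores, exact, atol=1e-8)

    def test_fixture_phenotypes_scored_symmetrically(self, fixture_data):
        """All four phenotypes are wired identically, so scores must tie."""
        g, _ = fixture_data
        starts = g.nodes_in_layer(LayerTag.TARGET)
        scores = phenotype_scores(g, starts)
        vals = [s.normalized for s in scores.values()]
        assert len(vals) == 4
        assert np.allclose(vals, vals[0])
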