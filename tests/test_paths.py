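"""Route enumeration, path-frequency scoring, and ranking."""

import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbnet import (
    LayeredGraph,
    LayerTag,
    Route,
    ValidationError,
    enumerate_routes,
    node_frequencies,
    path_score,
    rank_routes,
    score_routes,
)
from conftest import make_random_graph


def brute_force_triples(g, phenotype):
    """Independent oracle: connected (component, target, entity) triples.

    An entity counts when it is the queried phenotype itself, or a pathway/
    bioprocess whose target also carries an edge to the queried phenotype.
    """
    ph = f"PHENOTYPE:{phenotype}"
    triples = set()
    for s, t in g.edges:
        if g.layer_of(s) is not LayerTag.COMPONENT:
            continue
        for t2, ent in g.edges:
            if t2 != t:
                continue
            if ent == ph or (
                g.layer_of(ent) in (LayerTag.PATHWAY, LayerTag.BIOPROCESS)
                and (t, ph) in g.edges
            ):
                triples.add((s, t, ent))
    return triples


class TestEnumerateRoutes:
    def test_single_chain_single_route(self, chain_graph):
        found = enumerate_routes(chain_graph, "phen")
        assert {r.nodes for r in found} == {
            ("COMPONENT:c1", "TARGET:TNF", "PATHWAY:P1"),
            ("COMPONENT:c1", "TARGET:TNF", "PHENOTYPE:phen"),
        }

    def test_component_without_targets_yields_nothing(self):
        g = LayeredGraph()
        g.add_node(LayerTag.COMPONENT, "c1")
        g.add_node(LayerTag.PHENOTYPE, "phen")
        assert enumerate_routes(g, "phen") == []

    def test_unknown_phenotype_rejected(self, chain_graph):
        with pytest.raises(ValidationError):
            enumerate_routes(chain_graph, "nope")

    def test_routes_are_sorted(self, fixture_data):
        g, _ = fixture_data
        found = enumerate_routes(g, "blood circulation")
        assert found == sorted(found)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_triple_enumeration_oracle(self, seed):
        g = make_random_graph(random.Random(seed), n_targets=5, n_components=3, n_pathways=3)
        found = {r.nodes for r in enumerate_routes(g, "phen")}
        assert found == {tuple(t) for t in brute_force_triples(g, "phen")}

    def test_fixture_route_count_matches_oracle(self, fixture_data):
        g, _ = fixture_data
        for phen in ("blood circulation", "diabetes mellitus"):
            assert len(enumerate_routes(g, phen)) == len(brute_force_triples(g, phen))

    def test_four_layer_template_goes_through_pathways(self):
        g = LayeredGraph()
        c = g.add_node(LayerTag.COMPONENT, "c1")
        t = g.add_node(LayerTag.TARGET, "TNF")
        p = g.add_node(LayerTag.PATHWAY, "P1")
        ph = g.add_node(LayerTag.PHENOTYPE, "phen")
        g.add_edge(c, t)
        g.add_edge(t, p)
        g.add_edge(p, ph)
        found = enumerate_routes(g, "phen", layers=4)
        assert [r.nodes for r in found] == [(c, t, p, ph)]


class TestFrequenciesAndScore:
    def test_single_route_all_frequencies_one(self):
        freq, total = node_frequencies([Route(("a", "b", "c"))])
        assert total == 1 and set(freq.values()) == {1}

    def test_shared_node_counted_per_route(self):
        freq, total = node_frequencies([Route(("a", "b")), Route(("a", "c"))])
        assert freq["a"] == 2 and freq["b"] == 1 and total == 2

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValidationError):
            node_frequencies([])

    def test_singleton_corpus_scores_one(self):
        r = Route(("a", "b", "c"))
        freq, total = node_frequencies([r])
        assert path_score(r, freq, total) == 1.0

    def test_two_path_worked_example(self):
        """Corpus {(a,b),(a,c)}: score of (a,b) = (2/2 + 1/2)/2 = 0.75."""
        routes = [Route(("a", "b")), Route(("a", "c"))]
        freq, total = node_frequencies(routes)
        assert path_score(routes[0], freq, total) == pytest.approx(0.75)

    def test_missing_node_rejected(self):
        with pytest.raises(ValidationError):
            path_score(Route(("a", "x")), Counter({"a": 1}), 1)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.lists(st.sampled_from("abcdefgh"), min_size=2, max_size=4, unique=True),
            min_size=1,
            max_size=12,
        )
    )
    def test_score_bounds_and_frequency_recount(self, raw):
        """0 < score <= 1; frequencies equal brute-force membership counts."""
        routes = [Route(tuple(r)) for r in raw]
        table = score_routes(routes)
        for r, s in table.rows():
            assert 0 < s <= 1
            if s == 1.0:
                assert all(set(r.nodes) <= set(r2.nodes) for r2 in routes)
        for node, count in table.frequencies.items():
            assert count == sum(1 for r in routes if node in r.nodes)

    def test_adding_disjoint_route_lowers_score(self):
        routes = [Route(("a", "b")), Route(("a", "c"))]
        freq, total = node_frequencies(routes)
        before = path_score(routes[0], freq, total)
        grown = routes + [Route(("x", "y"))]
        freq2, total2 = node_frequencies(grown)
        assert freq2["a"] == freq["a"] and freq2["b"] == freq["b"]
        assert path_score(routes[0], freq2, total2) < before


class TestRankRoutes:
    def test_best_route_per_terminal_survives(self):
        routes = [
            Route(("c1", "t1", "b1")),
            Route(("c1", "t1", "b2")),
            Route(("c2", "t2", "b1")),
        ]
        ranked = rank_routes(score_routes(routes))
        terminals = [r.terminal for r, _ in ranked]
        assert sorted(terminals) == ["b1", "b2"]
        b1_winner = next(r for r, _ in ranked if r.terminal == "b1")
        assert b1_winner.nodes == ("c1", "t1", "b1")  # shares c1,t1 → higher score

    def test_distinct_terminals_pure_sort(self):
        routes = [Route(("c", "t", f"b{i}")) for i in range(4)]
        ranked = rank_routes(score_routes(routes))
        assert len(ranked) == 4
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_output_size_equals_distinct_terminals(self, seed):
        rng = random.Random(seed)
        routes = list(
            {
                Route((f"c{rng.randrange(3)}", f"t{rng.randrange(4)}", f"b{rng.randrange(4)}"))
                for _ in range(rng.randrange(1, 15))
            }
        )
        ranked = rank_routes(score_routes(routes))
        assert len(ranked) == len({r.terminal for r in routes})
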