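import pytest

from herbnet import LayeredGraph, LayerTag, build_red_ginseng_fixture


@pytest.fixture(scope="session")
def fixture_data():
    """Packaged red-ginseng graph + pathway collection (immutable; share)."""
    return build_red_ginseng_fixture()


@pytest.fixture
def chain_graph():
    """Minimal component→target→pathway→phenotype chain."""
    g = LayeredGraph()
    c = g.add_node(LayerTag.COMPONENT, "c1")
    t = g.add_node(LayerTag.TARGET, "TNF")
    p = g.add_node(LayerTag.PATHWAY, "P1")
    ph = g.add_node(LayerTag.PHENOTYPE, "phen")
    g.add_edge(c, t)
    g.add_edge(t, p)
    g.add_edge(t, ph)
    return g


def make_random_graph(rng, n_targets=6, n_components=2, n_pathways=2, p=0.5):
    """Small random layered graph for property tests."""
    g = LayeredGraph()
    comps = [g.add_node(LayerTag.COMPONENT, f"c{i}") for i in range(n_components)]
    tgts = [g.add_node(LayerTag.TARGET, f"T{i}") for i in range(n_targets)]
    pws = [g.add_node(LayerTag.PATHWAY, f"P{i}") for i in range(n_pathways)]
    ph = g.add_node(LayerTag.PHENOTYPE, "phen")
    for c in comps:
        for t in tgts:
            if rng.random() < p:
                g.add_edge(c, t)
    for t in tgts:
        for pw in pws:
            if rng.random() < p:
                g.add_edge(t, pw)
        if rng.random() < p:
            g.add_edge(t, ph)
    return g
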