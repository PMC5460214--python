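"""Steiner sub-network construction, edge classes and Monte-Carlo enrichment."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from samirnet.steiner import (
    annotate_edges,
    enrich_categories,
    enrichment_p,
    minimum_steiner_tree_exact,
    null_distribution,
    steiner_tree,
)


def _named(g):
    return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})


def test_path_graph_intermediate_becomes_steiner_node():
    g = nx.path_graph(["A", "B", "C"])
    sub = steiner_tree(g, {"A", "C"})
    assert sub.steiner_nodes == {"B"}
    assert sub.size == 3
    assert sub.tree_edges == {("A", "B"), ("B", "C")}


def test_star_graph_center_is_steiner_node():
    g = nx.star_graph(["H", "L1", "L2", "L3", "L4"])
    sub = steiner_tree(g, {"L1", "L2", "L3", "L4"})
    assert sub.steiner_nodes == {"H"}
    assert sub.size == 5


def test_absent_seeds_dropped_with_flag(caplog):
    g = nx.path_graph(["A", "B", "C"])
    with caplog.at_level("WARNING", logger="samirnet"):
        sub = steiner_tree(g, {"A", "C", "ZZZ"})
    assert sub.dropped_seeds == {"ZZZ"}
    assert sub.seed_nodes == {"A", "C"}


def test_disconnected_seeds_give_forest():
    g = nx.Graph([("A", "B"), ("C", "D")])
    sub = steiner_tree(g, {"A", "B", "C", "D"})
    assert sub.is_forest
    # |edges| = |nodes| - #components for a forest
    assert len(sub.tree_edges) == sub.size - 2


def test_tree_validity_random_graphs(rng):
    """Tree spans all retained seeds with |E| = |V| - #components."""
    for trial in range(30):
        g = _named(nx.gnp_random_graph(15, 0.2, seed=int(rng.integers(1 << 30))))
        nodes = sorted(g.nodes)
        seeds = list(rng.choice(nodes, size=4, replace=False))
        sub = steiner_tree(g, seeds)
        t = nx.Graph(list(sub.tree_edges))
        t.add_nodes_from(sub.nodes)
        assert set(sub.seed_nodes) <= set(t.nodes)
        n_comp = nx.number_connected_components(t)
        assert len(sub.tree_edges) == sub.size - n_comp
        # every seed pair in one graph component is connected in the tree
        for a, b in combinations(sub.seed_nodes, 2):
            if nx.has_path(g, a, b):
                assert nx.has_path(t, a, b)


def test_heuristic_never_beats_exact_and_usually_matches(rng):
    """On small instances the heuristic is >= the optimum, mostly equal."""
    equal = total = 0
    while total < 40:
        g = _named(nx.gnp_random_graph(10, 0.25, seed=int(rng.integers(1 << 30))))
        nodes = sorted(g.nodes)
        seeds = list(rng.choice(nodes, size=3, replace=False))
        if not all(nx.has_path(g, seeds[0], s) for s in seeds[1:]):
            continue  # exact oracle needs one component
        total += 1
        opt = minimum_steiner_tree_exact(g, seeds)
        heur = steiner_tree(g, seeds).size
        assert heur >= opt
        equal += heur == opt
    assert equal / total >= 0.9


def test_deterministic_given_inputs():
    g = _named(nx.gnp_random_graph(25, 0.15, seed=11))
    seeds = ["N01", "N07", "N19", "N23"]
    seeds = [s for s in seeds if s in g]
    a = steiner_tree(g, seeds)
    b = steiner_tree(g, list(reversed(seeds)))
    assert a.tree_edges == b.tree_edges  # seed order irrelevant


def test_edge_classes_triangle_inter():
    g = nx.Graph([("A", "B"), ("A", "C"), ("B", "C")])
    s1 = steiner_tree(g, {"A", "B"}, category="one")
    s2 = steiner_tree(g, {"C"}, category="two")
    s1, s2 = annotate_edges(g, [s1, s2])
    assert s1.tree_edges == {("A", "B")}
    assert s1.inter_edges == {("A", "C"), ("B", "C")}
    assert s1.intra_edges == frozenset()


def test_edge_classes_clique_intra():
    g = nx.complete_graph(["A", "B", "C", "D"])
    (s,) = annotate_edges(g, [steiner_tree(g, {"A", "B", "C", "D"}, category="c")])
    assert len(s.tree_edges) == 3
    assert len(s.intra_edges) == 3  # remaining clique edges
    assert s.inter_edges == frozenset()
    assert not (s.tree_edges & s.intra_edges)


def test_edge_classes_disjoint_subnetworks_no_inter():
    g = nx.Graph([("A", "B"), ("C", "D")])
    subs = [
        steiner_tree(g, {"A", "B"}, category="one"),
        steiner_tree(g, {"C", "D"}, category="two"),
    ]
    for s in annotate_edges(g, subs):
        assert s.inter_edges == frozenset()


def test_null_sizes_trivial_cases(rng):
    g = _named(nx.gnp_random_graph(20, 0.3, seed=3))
    assert (null_distribution(g, 1, 50, rng) == 1).all()
    gk = nx.complete_graph(["A", "B", "C", "D", "E"])
    assert (null_distribution(gk, 3, 50, rng) == 3).all()


def test_null_distribution_reproducible():
    g = _named(nx.gnp_random_graph(30, 0.12, seed=9))
    a = null_distribution(g, 4, 200, rng=123)
    b = null_distribution(g, 4, 200, rng=123)
    assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        null_distribution(g, 99, 10, rng=0)


def test_enrichment_p_extremes():
    assert enrichment_p(100, [1, 2, 3]) == pytest.approx(1.0)
    assert enrichment_p(0, np.arange(1, 201)) == pytest.approx(1 / 201)


def test_monte_carlo_p_matches_exhaustive_enumeration():
    """Tiny graph: MC p within 3 SE of the exact p over all C(n,k) seed sets."""
    g = _named(nx.gnp_random_graph(9, 0.35, seed=21))
    # restrict to the largest component so every draw yields one tree
    comp = sorted(max(nx.connected_components(g), key=len))
    g = g.subgraph(comp).copy()
    k = 3
    sizes = [steiner_tree(g, list(c)).size for c in combinations(sorted(g.nodes), k)]
    seeds_obs = sorted(g.nodes)[:k]
    obs = steiner_tree(g, seeds_obs).size
    exact_p = sum(s <= obs for s in sizes) / len(sizes)
    n_sim = 800
    null = null_distribution(g, k, n_sim, rng=5)
    mc_p = enrichment_p(obs, null)
    se = np.sqrt(exact_p * (1 - exact_p) / n_sim)
    assert abs(mc_p - exact_p) <= 3 * se + 2 / n_sim  # add-one correction slack


def test_p_valid_under_null(rng):
    """Seeds drawn from the null universe give p stochastically >= uniform."""
    g = _named(nx.barabasi_albert_graph(60, 2, seed=17))
    nodes = sorted(g.nodes)
    null = null_distribution(g, 4, 400, rng=7)
    ps = []
    for _ in range(200):
        seeds = rng.choice(nodes, size=4, replace=False)
        ps.append(enrichment_p(steiner_tree(g, list(seeds)).size, null))
    ps = np.array(ps)
    # empirical CDF of p at common alphas must not exceed alpha by much
    for alpha in (0.05, 0.1, 0.25, 0.5):
        assert (ps <= alpha).mean() <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 200)


def test_enrich_categories_planted_vs_scattered(sim_bundle):
    """A planted dense module is more coherent than a scattered control."""
    from samirnet.io import GeneSet

    graph = sim_bundle["network"]
    sets = [
        GeneSet(name, name, frozenset(genes))
        for name, genes in sim_bundle["gene_sets"].items()
    ]
    subs, results = enrich_categories(graph, sets, n_sim=300, rng=99)
    by_name = {r.category: r for r in results}
    assert by_name["planted_module"].p_value < by_name["scattered_control"].p_value
    assert by_name["planted_module"].observed_size <= by_name["scattered_control"].observed_size
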