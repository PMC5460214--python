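"""Steiner-tree sub-network extraction and Monte-Carlo functional enrichment.

Genes from one functional category (the *seeds*) are connected on the
protein-interaction graph through the minimum number of intermediate
("Steiner") nodes. The size of the resulting sub-network — seeds plus
Steiner nodes — measures the functional coherence of the category: tightly
interacting genes need few intermediates. Significance is assessed by
simulating random Steiner networks seeded with the same number of genes
drawn from a null universe and asking how often a sub-network of the
observed size or smaller arises by chance (add-one Monte-Carlo p-value).

The tree is built with the Takahashi–Matsuyama shortest-path heuristic
under unit edge weights (minimum node count objective): grow from the
lexicographically first seed and repeatedly attach the nearest unconnected
seed along a shortest path, breaking all ties lexicographically so the
result is deterministic. A weighted mode (edge cost = 1 - confidence) and
an exact subset-enumeration solver for small instances are also provided.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

log = logging.getLogger("samirnet")

__all__ = [
    "SteinerSubnetwork",
    "EnrichmentResult",
    "steiner_tree",
    "minimum_steiner_tree_exact",
    "annotate_edges",
    "null_distribution",
    "enrichment_p",
    "enrich_categories",
]


@dataclass
class SteinerSubnetwork:
    """A category's connecting sub-network on the interaction graph."""

    category: str
    seed_nodes: frozenset
    steiner_nodes: frozenset
    tree_edges: frozenset  # frozenset of 2-tuples (sorted endpoints)
    intra_edges: frozenset = frozenset()
    inter_edges: frozenset = frozenset()
    dropped_seeds: frozenset = frozenset()
    is_forest: bool = False  # seeds spanned multiple components

    @property
    def nodes(self) -> frozenset:
        return self.seed_nodes | self.steiner_nodes

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass
class EnrichmentResult:
    category: str
    observed_size: int
    n_seeds: int
    n_sim: int
    p_value: float
    null_sizes: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "category": self.category,
            "observed_size": self.observed_size,
            "n_seeds": self.n_seeds,
            "n_sim": self.n_sim,
            "p_value": self.p_value,
            "null_mean_size": float(np.mean(self.null_sizes)),
        }


def _sorted_adjacency(graph: nx.Graph) -> dict:
    """Neighbour lists in lexicographic order for deterministic traversal."""
    return {n: sorted(graph.neighbors(n)) for n in graph.nodes}


class _GraphIndex:
    """Reusable per-graph structures for repeated Steiner computations."""

    def __init__(self, graph: nx.Graph, weighted: bool = False):
        self.graph = graph
        self.adj = _sorted_adjacency(graph)
        self.weighted = weighted
        self.component_of = {}
        for i, comp in enumerate(
            sorted(nx.connected_components(graph), key=lambda c: min(c))
        ):
            for n in comp:
                self.component_of[n] = i


def _grow_component_tree(index: _GraphIndex, seeds: list) -> tuple[set, set]:
    """Takahashi–Matsuyama on one component; returns (tree nodes, tree edges)."""
    adj = index.adj
    tree_nodes = {seeds[0]}
    tree_edges: set = set()
    remaining = set(seeds[1:])
    while remaining:
        # multi-source shortest-path search from the current tree, visiting
        # neighbours in lexicographic order so parents (hence paths) are
        # deterministic
        if index.weighted:
            dist, parent = _dijkstra_from(index, tree_nodes)
        else:
            dist, parent = _bfs_from(adj, tree_nodes)
        # nearest unconnected seed; ties broken lexicographically
        best = min(
            (s for s in remaining if s in dist), key=lambda s: (dist[s], s), default=None
        )
        if best is None:  # unreachable seeds are the caller's problem
            break
        node = best
        while node not in tree_nodes:
            prev = parent[node]
            tree_edges.add(tuple(sorted((prev, node))))
            tree_nodes.add(node)
            node = prev
        remaining.discard(best)
    return tree_nodes, tree_edges


def _bfs_from(adj: dict, sources: set) -> tuple[dict, dict]:
    dist = {s: 0 for s in sources}
    parent = {}
    frontier = sorted(sources)
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    parent[v] = u
                    nxt.append(v)
        frontier = sorted(nxt)
    return dist, parent


def _dijkstra_from(index: _GraphIndex, sources: set) -> tuple[dict, dict]:
    g = index.graph
    dist, parent, done = {}, {}, set()
    heap = [(0.0, s, None) for s in sorted(sources)]
    heapq.heapify(heap)
    while heap:
        d, u, par = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        dist[u] = d
        if par is not None:
            parent[u] = par
        for v in index.adj[u]:
            if v in done:
                continue
            w = 1.0 - float(g[u][v].get("confidence", 0.0))
            heapq.heappush(heap, (d + max(w, 1e-9), v, u))
    return dist, parent


def steiner_tree(
    graph: nx.Graph,
    seeds,
    category: str = "",
    weighted: bool = False,
    _index: _GraphIndex | None = None,
) -> SteinerSubnetwork:
    """Approximate minimum-node Steiner tree over ``seeds``.

    Seeds absent from the graph are dropped with a warning. Seeds spread
    over several connected components yield a forest (one tree per
    component) with ``is_forest`` set.
    """
    seeds = {str(s) for s in seeds}
    present = sorted(s for s in seeds if s in graph)
    dropped = frozenset(seeds - set(present))
    if dropped:
        log.warning(
            "category %r: %d seed(s) absent from the graph dropped", category, len(dropped)
        )
    if not present:
        return SteinerSubnetwork(category, frozenset(), frozenset(), frozenset(),
                                 dropped_seeds=dropped)
    index = _index if _index is not None else _GraphIndex(graph, weighted=weighted)
    by_comp: dict[int, list] = {}
    for s in present:
        by_comp.setdefault(index.component_of[s], []).append(s)
    all_nodes: set = set()
    all_edges: set = set()
    for comp in sorted(by_comp):
        nodes, edges = _grow_component_tree(index, sorted(by_comp[comp]))
        all_nodes |= nodes
        all_edges |= edges
    seed_set = frozenset(present)
    return SteinerSubnetwork(
        category=category,
        seed_nodes=seed_set,
        steiner_nodes=frozenset(all_nodes - seed_set),
        tree_edges=frozenset(all_edges),
        dropped_seeds=dropped,
        is_forest=len(by_comp) > 1,
    )


def minimum_steiner_tree_exact(graph: nx.Graph, seeds) -> int:
    """Exact minimum node count of a connected subgraph spanning ``seeds``.

    Subset enumeration over candidate Steiner nodes — exponential; intended
    as a testing oracle for small instances (<= ~15 candidate nodes).
    """
    seeds = sorted({str(s) for s in seeds if s in graph})
    if not seeds:
        return 0
    comps = {frozenset(c) for c in nx.connected_components(graph)}
    comp_of = {}
    for c in comps:
        for n in c:
            comp_of[n] = c
    if len({comp_of[s] for s in seeds}) > 1:
        raise ValueError("exact solver requires all seeds in one component")
    candidates = sorted(comp_of[seeds[0]] - set(seeds))
    if len(candidates) > 18:
        raise ValueError("instance too large for subset enumeration")
    for extra in range(len(candidates) + 1):
        for subset in combinations(candidates, extra):
            nodes = set(seeds) | set(subset)
            if nx.is_connected(graph.subgraph(nodes)):
                return len(nodes)
    raise AssertionError("unreachable: full component is connected")


def annotate_edges(graph: nx.Graph, subnetworks: list[SteinerSubnetwork]) -> list[SteinerSubnetwork]:
    """Classify graph edges among sub-network members as tree/intra/inter.

    An edge is *tree* if any category uses it in its connecting tree,
    *intra* if both endpoints belong to one category's sub-network (and it
    is not a tree edge), and *inter* if its endpoints lie in different
    categories' sub-networks only. Classes are disjoint; returns new
    SteinerSubnetwork objects with ``intra_edges``/``inter_edges`` filled.
    """
    tree_edges = {e for sub in subnetworks for e in sub.tree_edges}
    membership: dict[str, set] = {}
    for i, sub in enumerate(subnetworks):
        for n in sub.nodes:
            membership.setdefault(n, set()).add(i)
    intra: dict[int, set] = {i: set() for i in range(len(subnetworks))}
    inter: dict[int, set] = {i: set() for i in range(len(subnetworks))}
    for u, v in graph.edges:
        if u not in membership or v not in membership:
            continue
        e = tuple(sorted((u, v)))
        if e in tree_edges:
            continue
        shared = membership[u] & membership[v]
        if shared:
            for i in shared:
                intra[i].add(e)
        else:
            for i in membership[u] | membership[v]:
                inter[i].add(e)
    out = []
    for i, sub in enumerate(subnetworks):
        out.append(
            SteinerSubnetwork(
                category=sub.category,
                seed_nodes=sub.seed_nodes,
                steiner_nodes=sub.steiner_nodes,
                tree_edges=sub.tree_edges,
                intra_edges=frozenset(intra[i]),
                inter_edges=frozenset(inter[i]),
                dropped_seeds=sub.dropped_seeds,
                is_forest=sub.is_forest,
            )
        )
    return out


def null_distribution(
    graph: nx.Graph,
    k: int,
    n_sim: int,
    rng: np.random.Generator | int,
    universe=None,
    weighted: bool = False,
) -> np.ndarray:
    """Sizes of Steiner sub-networks over random k-gene seed sets.

    Seeds are drawn uniformly without replacement from ``universe``
    (default: all graph nodes). Reproducible for a fixed generator/seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    universe = sorted(universe) if universe is not None else sorted(graph.nodes)
    universe = [u for u in universe if u in graph]
    if k > len(universe):
        raise ValueError(f"k={k} exceeds universe size {len(universe)}")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    index = _GraphIndex(graph, weighted=weighted)
    sizes = np.empty(n_sim, dtype=int)
    for i in range(n_sim):
        seeds = rng.choice(len(universe), size=k, replace=False)
        sub = steiner_tree(graph, [universe[j] for j in seeds], _index=index,
                           weighted=weighted)
        sizes[i] = sub.size
    return sizes


def enrichment_p(observed_size: int, null_sizes) -> float:
    """Add-one Monte-Carlo p: P(null size <= observed)."""
    null_sizes = np.asarray(null_sizes)
    if null_sizes.size == 0:
        raise ValueError("null distribution is empty")
    return float((1 + int((null_sizes <= observed_size).sum())) / (null_sizes.size + 1))


def enrich_categories(
    graph: nx.Graph,
    gene_sets,
    n_sim: int = 1000,
    rng: np.random.Generator | int = 0,
    universe=None,
    weighted: bool = False,
) -> tuple[list[SteinerSubnetwork], list[EnrichmentResult]]:
    """Full enrichment analysis over a collection of functional categories.

    For each gene set, builds the observed Steiner sub-network, simulates
    ``n_sim`` random sub-networks with the same retained seed count from
    ``universe`` and computes the add-one p-value. Returns edge-annotated
    sub-networks and per-category results, in gene-set iteration order.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    index = _GraphIndex(graph, weighted=weighted)
    subs, results = [], []
    for gs in gene_sets:
        sub = steiner_tree(graph, gs.genes, category=gs.name, _index=index,
                           weighted=weighted)
        subs.append(sub)
    subs = annotate_edges(graph, subs)
    for sub in subs:
        k = len(sub.seed_nodes)
        if k == 0:
            results.append(
                EnrichmentResult(sub.category, 0, 0, 0, 1.0, np.array([], dtype=int))
            )
            continue
        null = null_distribution(
            graph, k, n_sim, rng, universe=universe, weighted=weighted
        )
        results.append(
            EnrichmentResult(
                category=sub.category,
                observed_size=sub.size,
                n_seeds=k,
                n_sim=n_sim,
                p_value=enrichment_p(sub.size, null),
                null_sizes=null,
            )
        )
    return subs, results
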