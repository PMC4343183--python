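from itertools import combinations

import numpy as np
import pytest

from conftest import random_collection
from superpaths.clustering import (
    best_neighbor_edges,
    build_superpaths,
    core_edges,
    identical_groups,
    identity_edges,
    preprocess_absorption,
)
from superpaths.model import Pathway, PathwayCollection
from superpaths.similarity import jaccard, pairwise_graph


def _pathway(pid, genes, source="s", name=None):
    return Pathway(pid, source, name or pid, frozenset(genes))


def _genes(prefix, n):
    return {f"{prefix}{i}" for i in range(n)}


# ------------------------------------------------------------ components
# independent oracle: plain union-find over a brute-force edge list


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def partition(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return {frozenset(g) for g in groups.values()}


def _oracle_partition(coll, t1, t2, small_max=20, large_max=200, c_min=0.9):
    """Brute-force re-derivation of the SuperPath partition."""
    uf = _UnionFind(coll.ids)
    by_id = {p.id: p for p in coll}
    # absorption
    for s, l in combinations(coll, 2):
        for a, b in ((s, l), (l, s)):
            if (
                a.size < small_max
                and b.size < large_max
                and b.size >= a.size
                and len(a.genes & b.genes) / a.size >= c_min
            ):
                uf.union(a.id, b.id)
    # identity
    for a, b in combinations(coll, 2):
        if a.genes == b.genes:
            uf.union(a.id, b.id)
    # core
    for a, b in combinations(coll, 2):
        if jaccard(a.genes, b.genes) >= t2:
            uf.union(a.id, b.id)
    # best edges
    for p in coll:
        scores = {
            q.id: jaccard(p.genes, q.genes)
            for q in coll
            if q.id != p.id and q.genes != p.genes
        }
        scores = {q: s for q, s in scores.items() if s > 0}
        if not scores:
            continue
        best = max(scores.values())
        if best >= t1:
            for q, s in scores.items():
                if s == best:
                    uf.union(p.id, q)
    return uf.partition()


class TestPreprocessAbsorption:
    def test_small_inside_mid_sized_links(self):
        s = _pathway("s", _genes("g", 10))
        l = _pathway("l", _genes("g", 10) | _genes("h", 140))
        edges = preprocess_absorption(PathwayCollection([s, l]))
        assert edges == {("l", "s")}

    def test_partner_at_or_above_200_genes_excluded(self):
        s = _pathway("s", _genes("g", 10))
        l = _pathway("l", _genes("g", 10) | _genes("h", 240))
        assert preprocess_absorption(PathwayCollection([s, l])) == set()

    def test_pathway_of_25_genes_is_not_small(self):
        s = _pathway("s", _genes("g", 25))
        l = _pathway("l", _genes("g", 25) | _genes("h", 100))
        assert preprocess_absorption(PathwayCollection([s, l])) == set()

    def test_containment_below_cutoff_excluded(self):
        s = _pathway("s", _genes("g", 10))  # 8/10 contained
        l = _pathway("l", _genes("g", 8) | _genes("h", 100))
        assert preprocess_absorption(PathwayCollection([s, l])) == set()
        assert preprocess_absorption(
            PathwayCollection([s, l]), c_min=0.8
        ) == {("l", "s")}


class TestIdenticalGroups:
    def test_same_gene_sets_grouped(self):
        coll = PathwayCollection(
            [
                _pathway("a", _genes("g", 30), source="s1"),
                _pathway("b", _genes("g", 30), source="s2"),
                _pathway("c", _genes("h", 5)),
            ]
        )
        groups = identical_groups(coll)
        assert ["a", "b"] in groups and ["c"] in groups
        assert identity_edges(groups) == {("a", "b")}

    def test_all_distinct_no_edges(self):
        coll = random_collection(0, n=8, universe=40, min_size=5)
        assert identity_edges(identical_groups(coll)) == set()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hash_grouping_equals_quadratic_scan(self, seed):
        coll = random_collection(seed, n=25, universe=6, max_size=3)
        groups = {frozenset(g) for g in identical_groups(coll)}
        uf = _UnionFind(coll.ids)
        for a, b in combinations(coll, 2):
            if a.genes == b.genes:
                uf.union(a.id, b.id)
        assert groups == uf.partition()


class TestEdgeRules:
    def test_core_edges_filter_at_t2(self):
        coll = PathwayCollection(
            [
                # J(a,b) = 10/14 ~ 0.71; J(a,c) = 9/13 ~ 0.69
                _pathway("a", _genes("g", 12)),
                _pathway("b", _genes("g", 10) | _genes("x", 2)),
                _pathway("c", _genes("g", 9) | {"y0"}),
            ]
        )
        graph = pairwise_graph(coll, j_min=0.05)
        kept = core_edges(graph, 0.7)
        assert ("a", "b") in kept and ("a", "c") not in kept
        assert core_edges(graph, 0.05) == {
            (a, b) for a, b, _ in graph.edges()
        }

    def test_single_best_neighbor(self):
        coll = PathwayCollection(
            [
                # J(p,a) = 9/20 = 0.45 ; J(p,b) ~ 0.19 (below t1)
                _pathway("p", _genes("g", 13)),
                _pathway("a", _genes("g", 9) | _genes("x", 7)),
                _pathway("b", _genes("g", 6) | _genes("y", 18)),
            ]
        )
        graph = pairwise_graph(coll, j_min=0.05)
        genes = {p.id: p.genes for p in coll}
        assert best_neighbor_edges(graph, 0.3, genes) == {("a", "p")}
        # at a permissive t1, b's own best (p) joins as well
        assert ("b", "p") in best_neighbor_edges(graph, 0.1, genes)

    def test_tied_best_neighbors_all_join(self):
        coll = PathwayCollection(
            [
                _pathway("p", _genes("g", 10)),
                # both at J(p, .) = 4/11; mutually distinct sets
                _pathway("a", _genes("g", 4) | _genes("x", 1)),
                _pathway("b", _genes("g", 4) | _genes("y", 1)),
            ]
        )
        graph = pairwise_graph(coll, j_min=0.05)
        genes = {p.id: p.genes for p in coll}
        edges = best_neighbor_edges(graph, 0.3, genes)
        assert ("a", "p") in edges and ("b", "p") in edges

    def test_identical_copy_is_never_the_nearest_neighbor(self):
        coll = PathwayCollection(
            [
                _pathway("p", _genes("g", 10)),
                _pathway("twin", _genes("g", 10)),
                # J(p,d) = 5/15 ~ 0.33
                _pathway("d", _genes("g", 5) | _genes("x", 5)),
            ]
        )
        graph = pairwise_graph(coll, j_min=0.05)
        genes = {p.id: p.genes for p in coll}
        edges = best_neighbor_edges(graph, 0.3, genes)
        assert ("p", "twin") not in edges
        assert ("d", "p") in edges and ("d", "twin") in edges


class TestBuildSuperPaths:
    def test_chain_joins_through_best_edge(self):
        # J(A,B) = 0.75 core; J(B,C) = 0.35 is C's best
        a = _pathway("A", _genes("g", 15))
        b = _pathway("B", _genes("g", 15) | _genes("x", 5))
        c = _pathway("C", _genes("x", 5) | _genes("g", 4) | _genes("y", 6))
        assert round(jaccard(a.genes, b.genes), 2) == 0.75
        assert round(jaccard(b.genes, c.genes), 2) == 0.35
        clustering = build_superpaths(
            PathwayCollection([a, b, c]), t1=0.3, t2=0.7, absorption=False
        )
        assert len(clustering) == 1
        assert clustering.superpaths[0].members == frozenset("ABC")

    def test_disjoint_pathways_stay_singletons(self):
        coll = PathwayCollection(
            [_pathway(f"p{i}", _genes(f"u{i}_", 5)) for i in range(20)]
        )
        clustering = build_superpaths(coll, 0.3, 0.7)
        assert len(clustering) == 20
        assert clustering.n_singletons == 20

    def test_t1_above_t2_rejected(self, tiny_collection):
        with pytest.raises(ValueError):
            build_superpaths(tiny_collection, t1=0.8, t2=0.5)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("t1,t2", [(0.3, 0.7), (0.2, 0.4), (0.5, 0.5)])
    def test_partition_equals_union_find_oracle(self, seed, t1, t2):
        coll = random_collection(seed, n=12, universe=15, max_size=8)
        clustering = build_superpaths(coll, t1=t1, t2=t2)
        assert set(clustering.partition()) == _oracle_partition(coll, t1, t2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_order_independence(self, seed):
        coll = random_collection(seed, n=15, universe=20)
        rng = np.random.default_rng(seed + 99)
        perm = list(rng.permutation(len(coll)))
        shuffled = PathwayCollection([coll.pathways[i] for i in perm])
        a = build_superpaths(coll, 0.3, 0.7)
        b = build_superpaths(shuffled, 0.3, 0.7)
        assert set(a.partition()) == set(b.partition())
        assert {sp.id: sp.hub for sp in a} == {sp.id: sp.hub for sp in b}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equal_cutoffs_reduce_to_single_linkage(self, seed):
        """At t1 = t2 = T the partition is the connected components of
        the J >= T graph plus absorption/identity edges."""
        coll = random_collection(seed, n=14, universe=18)
        for t in (0.3, 0.5):
            clustering = build_superpaths(coll, t1=t, t2=t)
            uf = _UnionFind(coll.ids)
            for a, b in combinations(coll, 2):
                if jaccard(a.genes, b.genes) >= t:
                    uf.union(a.id, b.id)
            for s, l in preprocess_absorption(coll):
                uf.union(s, l)
            for group in identical_groups(coll):
                for x, y in zip(group, group[1:]):
                    uf.union(x, y)
            assert set(clustering.partition()) == uf.partition()

    @pytest.mark.parametrize("seed", [0, 1])
    def test_lower_cutoffs_never_split_clusters(self, seed):
        coll = random_collection(seed, n=15, universe=20)
        grid = [0.2, 0.4, 0.6, 0.8]
        for i, t2 in enumerate(grid):
            for t1 in grid[: i + 1]:
                n = len(build_superpaths(coll, t1, t2))
                for lower in grid:
                    if lower <= t1:
                        assert len(build_superpaths(coll, lower, t2)) <= n
                assert len(build_superpaths(coll, t1, t1)) <= n


class TestHubs:
    def test_star_center_is_hub(self):
        center = _pathway("c", _genes("g", 10))
        # each leaf shares 7 staggered genes with the center (J ~ 0.37)
        # but only ~6 with other leaves (J ~ 0.23, below both cutoffs)
        leaves = [
            _pathway(
                f"l{i}",
                {f"g{(i + k) % 10}" for k in range(7)} | _genes(f"x{i}_", 9),
            )
            for i in range(4)
        ]
        clustering = build_superpaths(
            PathwayCollection([center] + leaves), t1=0.3, t2=0.3
        )
        assert len(clustering) == 1
        assert clustering.superpaths[0].hub == "c"

    def test_degree_tie_goes_to_larger_gene_set(self):
        big = _pathway("big", _genes("g", 30) | _genes("x", 10))
        small = _pathway("small", _genes("g", 25))
        clustering = build_superpaths(
            PathwayCollection([small, big]), t1=0.3, t2=0.3
        )
        sp = clustering.superpaths[0]
        assert sp.members == frozenset({"big", "small"})
        assert sp.hub == "big"
        assert sp.name == "big"

    def test_singleton_is_its_own_hub(self):
        clustering = build_superpaths(
            PathwayCollection([_pathway("only", _genes("g", 5))]), 0.3, 0.7
        )
        assert clustering.superpaths[0].hub == "only"


class TestSuperPathInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_and_support(self, seed):
        coll = random_collection(seed, n=15, universe=20)
        clustering = build_superpaths(coll, 0.3, 0.7)
        seen: set[str] = set()
        for sp in clustering:
            assert sp.members
            assert not (seen & sp.members)
            seen |= sp.members
            union = frozenset().union(*(coll[m].genes for m in sp.members))
            assert sp.genes == union
            for g in sp.genes:
                assert 1 <= sp.support[g] <= len(sp.members)
                assert sp.support[g] == sum(
                    1 for m in sp.members if g in coll[m].genes
                )
        assert seen == set(coll.ids)
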