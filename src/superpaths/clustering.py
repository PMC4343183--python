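"""SuperPath construction: two-threshold similarity clustering.

A SuperPath is a connected component of the pathway corpus under the
union of four edge families:

1. *Absorption* edges: a pathway of fewer than ``small_max`` genes is
   connected to every larger pathway (below ``large_max`` genes) that
   contains at least ``c_min`` of its genes.  This compensates for the
   Jaccard coefficient's blindness to near-complete containment of a
   small set in a large one.
2. *Identity* edges: pathways with exactly equal gene sets are joined
   directly (and are excluded as nearest-neighbor candidates).
3. *Core* edges (upper cutoff ``t2``): every pair with ``J >= t2``,
   equivalent to single-linkage hierarchical clustering.
4. *Best* edges (lower cutoff ``t1``): each pathway joins its
   best-scoring non-identical neighbor(s) provided that best score is
   ``>= t1`` — nearest-neighbor graph generation, with all ties kept.

The construction depends only on the edge set, never on input order.
Each component's *hub* — the member with the most intra-component
edges, ties broken towards the larger gene set and then the smaller
id — names the SuperPath.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .model import Pathway, PathwayCollection
from .similarity import SimilarityGraph, containment, pairwise_graph

Edge = tuple[str, str]


def _edge(a: str, b: str) -> Edge:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class SuperPath:
    """One consolidated cluster: member pathway ids, their gene union,
    per-gene support counts (how many members contain the gene), and
    the hub whose name labels the cluster."""

    id: str
    members: frozenset[str]
    genes: frozenset[str]
    support: Mapping[str, int]
    hub: str
    name: str

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1

    def support_fraction(self, gene: str) -> float:
        """Fraction of member pathways containing ``gene`` (the graded
        per-gene evidence shown for each SuperPath)."""
        return self.support[gene] / len(self.members)


@dataclass
class Clustering:
    """A partition of all pathway ids into SuperPaths, together with
    the thresholds and the edge log that produced it."""

    superpaths: list[SuperPath]
    t1: float
    t2: float
    edge_log: set[Edge] = field(default_factory=set)

    def __iter__(self):
        return iter(self.superpaths)

    def __len__(self) -> int:
        return len(self.superpaths)

    @property
    def labels(self) -> dict[str, str]:
        """pathway id -> superpath id."""
        out: dict[str, str] = {}
        for sp in self.superpaths:
            for m in sp.members:
                out[m] = sp.id
        return out

    @property
    def n_singletons(self) -> int:
        return sum(1 for sp in self.superpaths if sp.is_singleton)

    @property
    def largest_size(self) -> int:
        return max(len(sp.members) for sp in self.superpaths)

    def partition(self) -> list[frozenset[str]]:
        return [sp.members for sp in self.superpaths]


def preprocess_absorption(
    collection: PathwayCollection,
    small_max: int = 20,
    large_max: int = 200,
    c_min: float = 0.9,
) -> set[Edge]:
    """Absorption edges: (small, larger) pairs with high containment.

    Pairs every pathway of size < ``small_max`` with every distinct
    pathway of size < ``large_max`` that is at least as large and
    contains >= ``c_min`` of its genes.  Both pathways remain cluster
    members; absorption adds connectivity, it deletes nothing.
    """
    if not 0 < c_min <= 1:
        raise ValueError("c_min must be in (0, 1]")
    small = [p for p in collection if p.size < small_max]
    large = [p for p in collection if p.size < large_max]
    edges: set[Edge] = set()
    for s in small:
        for l in large:
            if l.id == s.id or l.size < s.size:
                continue
            if containment(s.genes, l.genes) >= c_min:
                edges.add(_edge(s.id, l.id))
    return edges


def identical_groups(collection: PathwayCollection) -> list[list[str]]:
    """Group pathway ids by exact gene-set equality (hash bucketing)."""
    buckets: dict[frozenset[str], list[str]] = {}
    for p in collection:
        buckets.setdefault(p.genes, []).append(p.id)
    return [sorted(ids) for _, ids in sorted(
        buckets.items(), key=lambda kv: kv[1][0]
    )]


def identity_edges(groups: Iterable[list[str]]) -> set[Edge]:
    """Spanning edges (a chain) within each identical-set group."""
    edges: set[Edge] = set()
    for group in groups:
        for a, b in zip(group, group[1:]):
            edges.add(_edge(a, b))
    return edges


def core_edges(graph: SimilarityGraph, t2: float) -> set[Edge]:
    """All similarity edges at or above the upper cutoff."""
    if not 0 < t2 <= 1:
        raise ValueError("t2 must be in (0, 1]")
    return {_edge(a, b) for a, b, w in graph.edges() if w >= t2}


def best_neighbor_edges(
    graph: SimilarityGraph,
    t1: float,
    genes_by_id: Mapping[str, frozenset[str]],
) -> set[Edge]:
    """Nearest-neighbor edges at the lower cutoff.

    For each pathway, the best Jaccard score among neighbors with a
    *different* gene set is found; if it reaches ``t1``, an edge to
    every neighbor achieving that score is emitted (all ties join).
    Identical copies are never candidates — they are handled by the
    identity edges.  The result is independent of iteration order.
    """
    if not 0 < t1 <= 1:
        raise ValueError("t1 must be in (0, 1]")
    edges: set[Edge] = set()
    for p in graph.nodes:
        candidates = {
            q: w
            for q, w in graph.neighbors(p).items()
            if genes_by_id[q] != genes_by_id[p]
        }
        if not candidates:
            continue
        best = max(candidates.values())
        if best >= t1:
            for q, w in candidates.items():
                if w == best:
                    edges.add(_edge(p, q))
    return edges


def build_superpaths(
    collection: PathwayCollection,
    t1: float = 0.3,
    t2: float = 0.7,
    small_max: int = 20,
    large_max: int = 200,
    c_min: float = 0.9,
    absorption: bool = True,
    aux_edges_in_hub_degree: bool = True,
) -> Clustering:
    """Run the full consolidation and return the SuperPath partition.

    ``t1`` is the nearest-neighbor (best-edge) cutoff, ``t2`` the
    single-linkage (core-edge) cutoff; ``t1 <= t2``.  Pathways touched
    by no edge become singleton SuperPaths.  Cluster ids are derived
    from each component's smallest member id, so output is stable
    under any permutation of the input.
    """
    if t1 > t2:
        raise ValueError(f"t1 ({t1}) must not exceed t2 ({t2})")
    graph = pairwise_graph(collection, j_min=min(t1, t2))
    genes_by_id = {p.id: p.genes for p in collection}

    aux: set[Edge] = set()
    if absorption:
        aux |= preprocess_absorption(collection, small_max, large_max, c_min)
    aux |= identity_edges(identical_groups(collection))
    main = core_edges(graph, t2) | best_neighbor_edges(graph, t1, genes_by_id)
    edge_log = aux | main

    g = nx.Graph()
    g.add_nodes_from(collection.ids)
    g.add_edges_from(edge_log)

    superpaths: list[SuperPath] = []
    hub_edges = edge_log if aux_edges_in_hub_degree else main
    for component in nx.connected_components(g):
        members = frozenset(component)
        superpaths.append(
            _make_superpath(members, collection, hub_edges)
        )
    superpaths.sort(key=lambda sp: sp.id)
    return Clustering(superpaths=superpaths, t1=t1, t2=t2, edge_log=edge_log)


def _make_superpath(
    members: frozenset[str],
    collection: PathwayCollection,
    hub_edges: set[Edge],
) -> SuperPath:
    genes: set[str] = set()
    support: dict[str, int] = {}
    for m in members:
        for g in collection[m].genes:
            support[g] = support.get(g, 0) + 1
        genes |= collection[m].genes
    hub = _choose_hub(members, collection, hub_edges)
    return SuperPath(
        id=f"SP_{min(members)}",
        members=members,
        genes=frozenset(genes),
        support=support,
        hub=hub,
        name=collection[hub].name,
    )


def _choose_hub(
    members: frozenset[str],
    collection: PathwayCollection,
    hub_edges: set[Edge],
) -> str:
    """Most intra-cluster-connected member; ties go to the larger gene
    set, then to the smallest id."""
    degree = {m: 0 for m in members}
    for a, b in hub_edges:
        if a in degree and b in degree:
            degree[a] += 1
            degree[b] += 1
    return min(
        members,
        key=lambda m: (-degree[m], -collection[m].size, m),
    )


def assign_hub_names(
    clustering: Clustering,
    collection: PathwayCollection,
    aux_edges_in_hub_degree: bool = True,
) -> Clustering:
    """Recompute hubs/names from the edge log (e.g. after editing it)."""
    hub_edges = clustering.edge_log
    new = []
    for sp in clustering.superpaths:
        hub = _choose_hub(sp.members, collection, hub_edges)
        new.append(replace(sp, hub=hub, name=collection[hub].name))
    return Clustering(
        superpaths=new,
        t1=clustering.t1,
        t2=clustering.t2,
        edge_log=clustering.edge_log,
    )


# ---------------------------------------------------------------- output


def write_superpath_gmt(
    clustering: Clustering, path: str | Path
) -> None:
    """One line per SuperPath: id, ``SuperPath|<hub name>``, union genes."""
    with Path(path).open("w") as fh:
        for sp in clustering:
            genes = "\t".join(sorted(sp.genes))
            fh.write(f"{sp.id}\tSuperPath|{sp.name}\t{genes}\n")


def write_membership_table(
    clustering: Clustering,
    collection: PathwayCollection,
    path: str | Path,
) -> None:
    with Path(path).open("w") as fh:
        fh.write("superpath\tpathway\tsource\trole\n")
        for sp in clustering:
            for m in sorted(sp.members):
                role = "hub" if m == sp.hub else "member"
                fh.write(f"{sp.id}\t{m}\t{collection[m].source}\t{role}\n")


def write_support_table(clustering: Clustering, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("superpath\tgene\tsupport\tfraction\n")
        for sp in clustering:
            for g in sorted(sp.genes):
                fh.write(
                    f"{sp.id}\t{g}\t{sp.support[g]}\t"
                    f"{sp.support_fraction(g):.4f}\n"
                )
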