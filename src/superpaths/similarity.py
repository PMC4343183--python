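"""Gene-content and name similarity.

The consolidation method treats a pathway purely as a gene set, so
pathway-pathway similarity is the Jaccard coefficient
``J = |A ∩ B| / |A ∪ B|``, and the corpus-wide structure is a sparse
symmetric similarity graph built through an inverted gene→pathway
index (disjoint pairs are never enumerated).

Name similarity is the Jaccard coefficient of the two names' token
sets after stopword removal and Porter stemming; it is deliberately
kept separate from gene-content similarity so the two can be compared
(concordance analysis).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from ._stem import stem
from .model import PathwayCollection

#: Trivial words removed before name comparison.  Deliberately small:
#: articles, prepositions and connectives only.  Domain words such as
#: "pathway" or "signaling" are informative and kept by default; pass a
#: custom set to drop them.
DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    """a an and by de for from in into of on or the to via with within
    without""".split()
)

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """``|a ∩ b| / |a ∪ b|`` for two non-empty gene sets."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("jaccard is undefined for empty sets")
    inter = len(sa & sb)
    return inter / (len(sa) + len(sb) - inter)


def containment(small: Iterable[str], large: Iterable[str]) -> float:
    """Overlap relative to the smaller partner: ``|s ∩ l| / |s|``."""
    ss = set(small)
    if not ss:
        raise ValueError("containment is undefined for an empty set")
    return len(ss & set(large)) / len(ss)


def tokenize_name(
    name: str, stopwords: frozenset[str] = DEFAULT_STOPWORDS
) -> frozenset[str]:
    """Lower-case, split on non-alphanumeric runs, drop stopwords and
    single characters, stem the rest; duplicates collapse."""
    tokens = [t for t in _TOKEN_RE.split(name.lower()) if t]
    return frozenset(
        stem(t) for t in tokens if len(t) > 1 and t not in stopwords
    )


def name_similarity(
    a: str, b: str, stopwords: frozenset[str] = DEFAULT_STOPWORDS
) -> float:
    """Jaccard coefficient of the two names' stemmed token sets.

    An empty token set on either side scores 0 — absence of usable
    words is no evidence of similarity.
    """
    ta, tb = tokenize_name(a, stopwords), tokenize_name(b, stopwords)
    if not ta or not tb:
        return 0.0
    return jaccard(ta, tb)


@dataclass
class SimilarityGraph:
    """Sparse symmetric pathway-pathway Jaccard graph.

    Stores every pair with ``J >= j_min``; a weight of 1 occurs iff the
    two gene sets are equal.
    """

    j_min: float
    _adj: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self._adj)

    def add_node(self, node: str) -> None:
        self._adj.setdefault(node, {})

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValueError("self-edges are not allowed")
        if weight < self.j_min:
            raise ValueError(
                f"edge weight {weight} below storage threshold {self.j_min}"
            )
        self._adj.setdefault(a, {})[b] = weight
        self._adj.setdefault(b, {})[a] = weight

    def neighbors(self, node: str) -> dict[str, float]:
        return self._adj.get(node, {})

    def weight(self, a: str, b: str) -> float | None:
        return self._adj.get(a, {}).get(b)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Deterministic edge iteration: lexicographic pairs."""
        for a in sorted(self._adj):
            for b in sorted(self._adj[a]):
                if a < b:
                    yield a, b, self._adj[a][b]

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2


def pairwise_graph(
    collection: PathwayCollection, j_min: float = 0.05
) -> SimilarityGraph:
    """All pathway pairs with ``J >= j_min``, via an inverted index.

    For each pathway the intersection size with every overlapping
    pathway is accumulated gene-by-gene, so fully disjoint pairs cost
    nothing.
    """
    if not 0 < j_min <= 1:
        raise ValueError("j_min must be in (0, 1]")
    graph = SimilarityGraph(j_min=j_min)
    ids = collection.ids
    sizes = {p.id: p.size for p in collection}
    index: dict[str, list[str]] = {}
    for p in collection:
        graph.add_node(p.id)
        for g in p.genes:
            index.setdefault(g, []).append(p.id)
    position = {pid: i for i, pid in enumerate(ids)}
    for p in collection:
        inter: dict[str, int] = {}
        for g in p.genes:
            for q in index[g]:
                if position[q] > position[p.id]:
                    inter[q] = inter.get(q, 0) + 1
        for q, k in inter.items():
            j = k / (sizes[p.id] + sizes[q] - k)
            if j >= j_min:
                graph.add_edge(p.id, q, j)
    return graph


def write_edge_list(graph: SimilarityGraph, path: str | Path) -> None:
    """Tab-separated (id1, id2, J) in deterministic lexicographic order."""
    with Path(path).open("w") as fh:
        fh.write("id1\tid2\tjaccard\n")
        for a, b, w in graph.edges():
            fh.write(f"{a}\t{b}\t{w:.6g}\n")
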