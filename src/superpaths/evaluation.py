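"""Validation statistics for a SuperPath consolidation.

Three independent lines of evidence:

* **Novel gene pairs vs pseudo-SuperPath controls.**  Consolidation
  creates gene pairs that share a SuperPath but never shared a single
  pathway.  If these pairs are biologically meaningful they should
  carry more external evidence (shared publications, protein-protein
  interaction scores) than pairs from size-matched random gene sets
  ("pseudo-SuperPaths").  Compared with a one-sided two-sample
  Kolmogorov-Smirnov test plus per-bin fold ratios.
* **Over-representation analysis (ORA).**  A SuperPath should score at
  least as well as its constituent pathways against differential-
  expression query sets; the per-query difference of ``-log10 p``
  (upper-tail hypergeometric) quantifies this.
* **Name/content concordance.**  A 2x2 contingency of name similarity
  vs gene-content similarity over all pathway pairs, showing how
  weakly names predict content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .clustering import Clustering, SuperPath
from .model import Pathway, PathwayCollection
from .similarity import DEFAULT_STOPWORDS, jaccard, name_similarity

Pair = tuple[str, str]


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


class PairEvidence:
    """Symmetric gene-pair -> evidence value mapping.

    ``kind`` is ``"count"`` (shared publications, non-negative ints)
    or ``"score"`` (PPI confidence in [0, 1]).  Pairs absent from the
    mapping score ``default`` (0 for sparse file-backed tables; a
    callable for dense synthetic models).
    """

    def __init__(
        self,
        values: Mapping[Pair, float] | None = None,
        kind: str = "count",
        default: float | Callable[[Pair], float] = 0,
    ) -> None:
        if kind not in ("count", "score"):
            raise ValueError("kind must be 'count' or 'score'")
        self.kind = kind
        self.default = default
        self._values: dict[Pair, float] = {}
        if values:
            for (a, b), v in values.items():
                self.set(a, b, v)

    def _check(self, value: float) -> float:
        if self.kind == "count":
            if value < 0 or value != int(value):
                raise ValueError(f"count evidence must be a non-negative "
                                 f"integer, got {value}")
            return int(value)
        if not 0 <= value <= 1:
            raise ValueError(f"score evidence must lie in [0, 1], got {value}")
        return float(value)

    def set(self, a: str, b: str, value: float) -> None:
        if a == b:
            raise ValueError("self-pairs carry no evidence")
        self._values[_pair(a, b)] = self._check(value)

    def get(self, a: str, b: str) -> float:
        key = _pair(a, b)
        if key in self._values:
            return self._values[key]
        if callable(self.default):
            return self.default(key)
        return self.default

    def __len__(self) -> int:
        return len(self._values)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairEvidence":
        """Read a (geneA, geneB, value) table; the header line declares
        the evidence type as ``#kind=count`` or ``#kind=score``."""
        path = Path(path)
        kind = "count"
        values: dict[Pair, float] = {}
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "kind=" in line:
                        kind = line.split("kind=", 1)[1].strip()
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(
                        f"{path.name}:{lineno}: expected 3 fields"
                    )
                values[_pair(fields[0], fields[1])] = float(fields[2])
        return cls(values, kind=kind)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"#kind={self.kind}\n")
            for (a, b), v in sorted(self._values.items()):
                fh.write(f"{a}\t{b}\t{v:g}\n")


# ------------------------------------------------------- novel gene pairs


def within_pathway_pairs(collection: PathwayCollection) -> set[Pair]:
    pairs: set[Pair] = set()
    for p in collection:
        for a, b in combinations(sorted(p.genes), 2):
            pairs.add((a, b))
    return pairs


def novel_gene_pairs(
    clustering: Clustering, collection: PathwayCollection
) -> set[Pair]:
    """Gene pairs sharing >= 1 SuperPath union but no single pathway."""
    known = within_pathway_pairs(collection)
    novel: set[Pair] = set()
    for sp in clustering:
        if sp.n_members < 2:
            continue
        for a, b in combinations(sorted(sp.genes), 2):
            if (a, b) not in known:
                novel.add((a, b))
    return novel


def pseudo_superpaths(
    clustering: Clustering,
    collection: PathwayCollection,
    annotated_universe: Iterable[str],
    seed: int,
) -> tuple[PathwayCollection, Clustering]:
    """Size-matched random controls for the real SuperPaths.

    For each SuperPath, the same number of genes is sampled uniformly
    without replacement from the annotated universe (genes with any
    pathway annotation); each member pathway's gene count is mirrored
    by resampling within the pseudo-set, so novel-pair extraction is
    well defined on the control.  Returns the pseudo pathway
    collection and a pseudo clustering over it; deterministic under
    ``seed``.
    """
    universe = sorted(set(annotated_universe))
    biggest = max(len(sp.genes) for sp in clustering)
    if len(universe) < biggest:
        raise ValueError(
            f"annotated universe ({len(universe)}) smaller than the "
            f"largest SuperPath union ({biggest})"
        )
    rng = np.random.default_rng(seed)
    pathways: list[Pathway] = []
    superpaths: list[SuperPath] = []
    for i, sp in enumerate(sorted(clustering, key=lambda s: s.id)):
        genes = [str(g) for g in
                 rng.choice(universe, size=len(sp.genes), replace=False)]
        member_ids = []
        support: dict[str, int] = {}
        for j, m in enumerate(sorted(sp.members)):
            k = collection[m].size
            gs = frozenset(
                str(g) for g in rng.choice(genes, size=k, replace=False)
            )
            pid = f"pseudo_{i}_{j}"
            member_ids.append(pid)
            for g in gs:
                support[g] = support.get(g, 0) + 1
            pathways.append(
                Pathway(pid, "pseudo", f"pseudo member of {sp.id}", gs)
            )
        superpaths.append(
            SuperPath(
                id=f"pseudo_{i}",
                members=frozenset(member_ids),
                genes=frozenset(genes),
                support=support,
                hub=member_ids[0],
                name=f"pseudo {sp.id}",
            )
        )
    return (
        PathwayCollection(pathways),
        Clustering(superpaths=superpaths, t1=clustering.t1, t2=clustering.t2),
    )


# ------------------------------------------------------------ KS contrast


@dataclass
class KSResult:
    statistic: float
    pvalue: float
    fold_ratios: list[tuple[float, float, float]]  # (bin lo, bin hi, ratio)
    n: int


def ks_compare(
    test: Sequence[float],
    control: Sequence[float],
    seed: int,
    bin_width: float = 10.0,
) -> KSResult:
    """One-sided KS test of whether ``test`` is stochastically greater
    than ``control``.

    The control (the larger set) is first downsampled without
    replacement to the test's size.  Also returns per-bin test/control
    count ratios on bins ``(0, w], (w, 2w], ...``; an empty control
    bin is treated as holding one observation so the ratio stays
    finite.
    """
    test = list(test)
    control = list(control)
    if not test or not control:
        raise ValueError("both samples must be non-empty")
    if len(control) < len(test):
        raise ValueError(
            "control must be at least as large as the test set"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(control), size=len(test), replace=False)
    control_ds = [control[i] for i in idx]
    # alternative='less': the test sample's CDF lies below the
    # control's, i.e. test values are stochastically greater.
    ks = stats.ks_2samp(test, control_ds, alternative="less")

    top = max(max(test), max(control_ds))
    ratios: list[tuple[float, float, float]] = []
    nbins = int(math.ceil(top / bin_width)) if top > 0 else 0
    for k in range(nbins):
        lo, hi = k * bin_width, (k + 1) * bin_width
        t = sum(1 for v in test if lo < v <= hi)
        c = sum(1 for v in control_ds if lo < v <= hi)
        if t == 0 and c == 0:
            continue
        ratios.append((lo, hi, t / (c if c > 0 else 1)))
    return KSResult(
        statistic=float(ks.statistic),
        pvalue=float(ks.pvalue),
        fold_ratios=ratios,
        n=len(test),
    )


# --------------------------------------------------------------------- ORA


def ora_pvalue(
    query: Iterable[str], target: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric probability of the observed overlap.

    ``P(X >= |query ∩ target|)`` with ``X ~ Hypergeom(|universe|,
    |target|, |query|)`` — the classical one-sided over-representation
    test.
    """
    q, t, u = set(query), set(target), set(universe)
    if not q or not t or not u:
        raise ValueError("query, target and universe must be non-empty")
    if not q <= u or not t <= u:
        raise ValueError("query and target must be subsets of the universe")
    k = len(q & t)
    return float(stats.hypergeom.sf(k - 1, len(u), len(t), len(q)))


def enrichment_delta(
    superpath: SuperPath,
    collection: PathwayCollection,
    query_sets: Sequence[Iterable[str]],
    universe: Iterable[str],
) -> list[float]:
    """Per-query gain of the SuperPath over its constituents.

    ``delta = -log10 p(superpath) - mean_i( -log10 p(pathway_i) )``;
    positive values mean the consolidated set scores better than its
    average constituent.
    """
    if superpath.n_members < 2:
        raise ValueError("enrichment contrast needs >= 2 member pathways")
    u = set(universe)
    deltas: list[float] = []
    for query in query_sets:
        q = set(query) & u
        if not q:
            continue
        p_sp = ora_pvalue(q, superpath.genes & u, u)
        p_members = [
            ora_pvalue(q, collection[m].genes & u, u)
            for m in sorted(superpath.members)
        ]
        deltas.append(
            -math.log10(p_sp) - float(
                np.mean([-math.log10(p) for p in p_members])
            )
        )
    return deltas


def two_member_cohort(
    clustering: Clustering,
    collection: PathwayCollection,
    j_max: float = 0.6,
) -> list[SuperPath]:
    """SuperPaths with exactly two members whose pairwise Jaccard is
    below ``j_max`` — relatively dissimilar pairs, where consolidation
    has the most to prove."""
    cohort = []
    for sp in clustering:
        if sp.n_members != 2:
            continue
        a, b = sorted(sp.members)
        if jaccard(collection[a].genes, collection[b].genes) < j_max:
            cohort.append(sp)
    return cohort


# ------------------------------------------------------------ concordance


@dataclass(frozen=True)
class Contingency2x2:
    """Name similarity vs gene-content similarity over pathway pairs."""

    similar_name_similar_genes: int
    similar_name_other_genes: int
    other_name_similar_genes: int
    other_name_other_genes: int

    @property
    def total(self) -> int:
        return (
            self.similar_name_similar_genes
            + self.similar_name_other_genes
            + self.other_name_similar_genes
            + self.other_name_other_genes
        )

    @property
    def pct_similar_genes_given_similar_name(self) -> float:
        """Of pairs with similar names, the % with similar gene content."""
        denom = self.similar_name_similar_genes + self.similar_name_other_genes
        return 100.0 * self.similar_name_similar_genes / denom

    @property
    def pct_similar_name_given_similar_genes(self) -> float:
        """Of pairs with similar gene content, the % with similar names."""
        denom = self.similar_name_similar_genes + self.other_name_similar_genes
        return 100.0 * self.similar_name_similar_genes / denom


def name_content_contingency(
    collection: PathwayCollection,
    name_cutoff: float = 0.5,
    gene_cutoff: float = 0.5,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> Contingency2x2:
    """Classify every unordered pathway pair by name similarity
    (>= ``name_cutoff``) and gene-content Jaccard (>= ``gene_cutoff``)."""
    if not 0 < name_cutoff <= 1 or not 0 < gene_cutoff <= 1:
        raise ValueError("cutoffs must lie in (0, 1]")
    ss = sn = ns = nn = 0
    pathways = list(collection)
    for a, b in combinations(pathways, 2):
        similar_name = name_similarity(a.name, b.name, stopwords) >= name_cutoff
        similar_genes = jaccard(a.genes, b.genes) >= gene_cutoff
        if similar_name and similar_genes:
            ss += 1
        elif similar_name:
            sn += 1
        elif similar_genes:
            ns += 1
        else:
            nn += 1
    return Contingency2x2(
        similar_name_similar_genes=ss,
        similar_name_other_genes=sn,
        other_name_similar_genes=ns,
        other_name_other_genes=nn,
    )
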