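"""Pathway collections and GMT input/output.

A :class:`Pathway` is one named gene set from one source; a
:class:`PathwayCollection` is the multi-source corpus that the
consolidation algorithm operates on.  Collections are read from and
written to GMT, the de-facto tab-separated gene-set exchange format
(one set per line: id, description, gene symbols).  Because GMT has no
source column, the description field encodes ``source|name``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCE_SEP = "|"


class GMTParseError(ValueError):
    """Raised for a malformed GMT line or a duplicated pathway id."""


@dataclass(frozen=True)
class Pathway:
    """One gene set: an id unique within its collection, a source label,
    a free-text name and a non-empty set of gene symbols."""

    id: str
    source: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.id!r} has an empty gene set")
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def size(self) -> int:
        return len(self.genes)


class PathwayCollection:
    """An ordered multi-source corpus of pathways with unique ids."""

    def __init__(self, pathways: Iterable[Pathway] = ()) -> None:
        self.pathways: list[Pathway] = list(pathways)
        self._by_id: dict[str, Pathway] = {}
        for p in self.pathways:
            if p.id in self._by_id:
                raise GMTParseError(f"duplicate pathway id {p.id!r}")
            self._by_id[p.id] = p

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._by_id[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pathways]

    @property
    def universe(self) -> frozenset[str]:
        """All genes appearing in at least one pathway."""
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return frozenset(out)

    @property
    def sources(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pathways:
            seen.setdefault(p.source)
        return list(seen)

    def subset(self, ids: Iterable[str]) -> "PathwayCollection":
        wanted = set(ids)
        return PathwayCollection(p for p in self.pathways if p.id in wanted)


def read_gmt(path: str | Path, normalize: bool = True) -> PathwayCollection:
    """Read a GMT file into a collection.

    Field 1 is the pathway id, field 2 is parsed as ``source|name``
    (source defaults to ``unknown`` when no separator is present),
    fields 3+ are gene symbols.  Duplicate symbols within a line are
    collapsed; with ``normalize`` symbols are upper-cased and stripped.
    """
    path = Path(path)
    pathways: list[Pathway] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            pid, desc = fields[0], fields[1]
            if SOURCE_SEP in desc:
                source, name = desc.split(SOURCE_SEP, 1)
            else:
                source, name = "unknown", desc
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if normalize:
                genes = [g.upper() for g in genes]
            if not genes:
                raise GMTParseError(
                    f"{path.name}:{lineno}: pathway {pid!r} has no genes"
                )
            pathways.append(Pathway(pid, source, name, frozenset(genes)))
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    """Write a collection as GMT; re-reading reproduces it exactly.

    Tabs inside a name would corrupt the format, so they are replaced
    with spaces (with a warning).
    """
    path = Path(path)
    with path.open("w") as fh:
        for p in collection:
            name = p.name
            if "\t" in name:
                logger.warning(
                    "pathway %s: tab in name replaced by space", p.id
                )
                name = name.replace("\t", " ")
            genes = "\t".join(sorted(p.genes))
            fh.write(f"{p.id}\t{p.source}{SOURCE_SEP}{name}\t{genes}\n")


def source_summary(
    collection: PathwayCollection, ddof: int = 0
) -> pd.DataFrame:
    """Per-source pathway count, distinct-gene count and size statistics.

    ``ddof=0`` (population standard deviation) by default; pass
    ``ddof=1`` for the sample formula.
    """
    rows = []
    for source in collection.sources:
        members = [p for p in collection if p.source == source]
        sizes = [p.size for p in members]
        union: set[str] = set()
        for p in members:
            union |= p.genes
        mean = sum(sizes) / len(sizes)
        if len(sizes) > ddof:
            var = sum((s - mean) ** 2 for s in sizes) / (len(sizes) - ddof)
            sd = math.sqrt(var)
        else:
            sd = float("nan")
        rows.append(
            {
                "source": source,
                "n_pathways": len(members),
                "n_genes": len(union),
                "mean_size": mean,
                "sd_size": sd,
            }
        )
    return pd.DataFrame(rows).set_index("source")


def coverage_curve(
    collection: PathwayCollection,
    source_order: Sequence[str] | None = None,
) -> list[int]:
    """Cumulative distinct-gene counts as sources are added.

    Entry ``k`` is the size of the union of the first ``k`` sources'
    gene repertoires.  The default order is descending per-source gene
    count, which makes the asymptote of the curve visible.
    """
    per_source: dict[str, set[str]] = {}
    for p in collection:
        per_source.setdefault(p.source, set()).update(p.genes)
    if source_order is None:
        source_order = sorted(
            per_source, key=lambda s: (-len(per_source[s]), s)
        )
    else:
        unknown = [s for s in source_order if s not in per_source]
        if unknown:
            raise KeyError(f"unknown source label(s): {unknown}")
    curve: list[int] = []
    seen: set[str] = set()
    for s in source_order:
        seen |= per_source[s]
        curve.append(len(seen))
    return curve


def membership_matrix(collection: PathwayCollection) -> pd.DataFrame:
    """Binary pathway x gene incidence matrix.

    Rows are pathway ids (collection order), columns the sorted gene
    universe; row sums equal pathway sizes and column sums equal
    per-gene pathway counts.
    """
    genes = sorted(collection.universe)
    col = {g: j for j, g in enumerate(genes)}
    mat = np.zeros((len(collection), len(genes)), dtype=np.int8)
    for i, p in enumerate(collection):
        for g in p.genes:
            mat[i, col[g]] = 1
    return pd.DataFrame(mat, index=collection.ids, columns=genes)
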