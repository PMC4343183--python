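"""Threshold selection: the uniqueness/informativeness objective and
dilution-resampling stability.

Two antagonistic log-scale scores steer the choice of the cutoff pair
``(t1, t2)``:

* **Uniqueness** ``U(s) = log10( mean_{g in G_s} 1 / N_sp(g) )`` for a
  SuperPath with gene union ``G_s``, where ``N_sp(g)`` counts the
  SuperPaths whose union contains ``g``.  ``U(s) = 0`` iff every gene
  of ``s`` occurs nowhere else; redundancy across clusters drives it
  down.  ``U_S`` is the unweighted mean over SuperPaths.
* **Informativeness** ``I(g) = log10( mean_{s ∋ g} 1 / |G_s| )`` for a
  gene ``g`` over the SuperPaths containing it.  Merging everything
  into one giant cluster drives ``I_S`` (the unweighted mean over
  genes) towards ``log10(1/|universe|)``.

Merging clusters can only raise ``U_S`` and lower ``I_S``, so their
sum is maximised at a balance point; a grid search over ``(t1, t2)``
finds it.  The upper cutoff is then refined by dilution resampling:
recluster random pathway subsets (75% and 90% by default) and measure
the fraction of full-data co-cluster pairs recovered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .clustering import Clustering, build_superpaths
from .model import PathwayCollection

Pair = tuple[str, str]


# ------------------------------------------------------------- objective


def uniqueness_from_unions(
    unions: Sequence[frozenset[str]],
) -> tuple[list[float], float]:
    """Per-cluster U values and their unweighted mean, from gene unions."""
    n_sp: dict[str, int] = {}
    for u in unions:
        for g in u:
            n_sp[g] = n_sp.get(g, 0) + 1
    per_cluster = [
        math.log10(sum(1.0 / n_sp[g] for g in u) / len(u)) for u in unions
    ]
    return per_cluster, float(np.mean(per_cluster))


def informativeness_from_unions(
    unions: Sequence[frozenset[str]],
) -> tuple[dict[str, float], float]:
    """Per-gene I values and their unweighted mean, from gene unions."""
    sizes = [len(u) for u in unions]
    acc: dict[str, list[int]] = {}
    for u, n in zip(unions, sizes):
        for g in u:
            acc.setdefault(g, []).append(n)
    per_gene = {
        g: math.log10(sum(1.0 / n for n in ns) / len(ns))
        for g, ns in acc.items()
    }
    return per_gene, float(np.mean(list(per_gene.values())))


def superpath_uniqueness(
    clustering: Clustering,
) -> tuple[dict[str, float], float]:
    """U per SuperPath (keyed by id) and the mean U_S."""
    if not clustering.superpaths:
        raise ValueError("empty clustering")
    unions = [sp.genes for sp in clustering]
    values, mean = uniqueness_from_unions(unions)
    return {sp.id: v for sp, v in zip(clustering, values)}, mean


def gene_informativeness(
    clustering: Clustering,
) -> tuple[dict[str, float], float]:
    """I per gene (genes with no pathway annotation are not scored)
    and the mean I_S."""
    unions = [sp.genes for sp in clustering]
    return informativeness_from_unions(unions)


# ------------------------------------------------------------ grid search


@dataclass(frozen=True)
class GridEntry:
    t1: float
    t2: float
    u_s: float
    i_s: float

    @property
    def objective(self) -> float:
        return self.u_s + self.i_s


@dataclass
class ThresholdGrid:
    entries: list[GridEntry]

    @property
    def argmax(self) -> GridEntry:
        best = max(e.objective for e in self.entries)
        # deterministic tie-break: smallest (t1, t2) among maxima
        return min(
            (e for e in self.entries if e.objective == best),
            key=lambda e: (e.t1, e.t2),
        )

    def to_table(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("t1\tt2\tU_S\tI_S\tobjective\n")
            for e in self.entries:
                fh.write(
                    f"{e.t1:.3g}\t{e.t2:.3g}\t{e.u_s:.6f}\t"
                    f"{e.i_s:.6f}\t{e.objective:.6f}\n"
                )

    def to_heatmap(self, path: str | Path) -> None:
        """Render the objective surface over (t1, t2) to an image file."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t1s = sorted({e.t1 for e in self.entries})
        t2s = sorted({e.t2 for e in self.entries})
        grid = np.full((len(t1s), len(t2s)), np.nan)
        for e in self.entries:
            grid[t1s.index(e.t1), t2s.index(e.t2)] = e.objective
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(grid, origin="lower", aspect="auto",
                       extent=(min(t2s), max(t2s), min(t1s), max(t1s)))
        ax.set_xlabel("t2 (core-edge cutoff)")
        ax.set_ylabel("t1 (best-edge cutoff)")
        fig.colorbar(im, ax=ax, label="U_S + I_S")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


DEFAULT_GRID = [round(0.1 * k, 1) for k in range(1, 11)]


def grid_search(
    collection: PathwayCollection,
    t1_values: Sequence[float] | None = None,
    t2_values: Sequence[float] | None = None,
    **cluster_kwargs,
) -> ThresholdGrid:
    """Score ``U_S + I_S`` over every admissible ``(t1 <= t2)`` pair.

    The diagonal ``t1 == t2`` corresponds to pure single-linkage
    hierarchical clustering.
    """
    t1_values = list(t1_values if t1_values is not None else DEFAULT_GRID)
    t2_values = list(t2_values if t2_values is not None else DEFAULT_GRID)
    if not t1_values or not t2_values:
        raise ValueError("empty threshold grid")
    entries: list[GridEntry] = []
    for t1 in sorted(t1_values):
        for t2 in sorted(t2_values):
            if t1 > t2:
                continue
            clustering = build_superpaths(
                collection, t1=t1, t2=t2, **cluster_kwargs
            )
            _, u_s = superpath_uniqueness(clustering)
            _, i_s = gene_informativeness(clustering)
            entries.append(GridEntry(t1=t1, t2=t2, u_s=u_s, i_s=i_s))
    if not entries:
        raise ValueError("grid contains no admissible (t1 <= t2) pair")
    return ThresholdGrid(entries=entries)


# --------------------------------------------------------------- stability


def co_cluster_pairs(clustering: Clustering) -> set[Pair]:
    """Unordered pathway pairs sharing a SuperPath."""
    pairs: set[Pair] = set()
    for sp in clustering:
        for a, b in combinations(sorted(sp.members), 2):
            pairs.add((a, b))
    return pairs


@dataclass
class StabilityRow:
    t2: float
    dilution: float
    recoveries: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.recoveries)) if self.recoveries else math.nan

    @property
    def sd(self) -> float:
        if len(self.recoveries) < 2:
            return math.nan
        return float(np.std(self.recoveries, ddof=1))


@dataclass
class StabilityResult:
    rows: list[StabilityRow]
    n_skipped: int = 0

    def mean_recovery(self, t2: float, dilution: float) -> float:
        for r in self.rows:
            if r.t2 == t2 and r.dilution == dilution:
                return r.mean
        raise KeyError((t2, dilution))

    def best_t2(self, dilution: float | None = None) -> float:
        """t2 with the highest mean recovery (averaged over dilutions
        unless one is given); ties go to the smaller t2."""
        rows = [
            r for r in self.rows
            if dilution is None or r.dilution == dilution
        ]
        means: dict[float, list[float]] = {}
        for r in rows:
            means.setdefault(r.t2, []).append(r.mean)
        return min(
            means, key=lambda t2: (-float(np.mean(means[t2])), t2)
        )

    def to_table(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("t2\tdilution\tn_reps\tmean_recovery\tsd\n")
            for r in self.rows:
                fh.write(
                    f"{r.t2:.3g}\t{r.dilution:.3g}\t{len(r.recoveries)}\t"
                    f"{r.mean:.6f}\t{r.sd:.6f}\n"
                )


def stability_scan(
    collection: PathwayCollection,
    t1: float,
    t2_values: Sequence[float],
    dilutions: Iterable[float] = (0.75, 0.9),
    reps: int = 100,
    seed: int = 0,
    **cluster_kwargs,
) -> StabilityResult:
    """Dilution-resampling stability of the clustering across ``t2``.

    For each ``t2``, the full-data co-cluster pair set is computed
    once; each replicate then reclusters a random pathway subset of
    the given dilution and reports the fraction of full-data pairs
    (restricted to the sampled pathways) that are still co-clustered.
    Replicates whose restriction holds no pairs contribute no
    observation.  Deterministic under ``seed``.
    """
    dilutions = list(dilutions)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if any(not 0 < d <= 1 for d in dilutions):
        raise ValueError("dilutions must lie in (0, 1]")
    ids = collection.ids
    n = len(ids)
    rows: list[StabilityRow] = []
    n_skipped = 0
    for t2 in t2_values:
        full = build_superpaths(collection, t1=t1, t2=t2, **cluster_kwargs)
        p_full = co_cluster_pairs(full)
        rng = np.random.default_rng(seed)
        for dilution in dilutions:
            k = int(math.floor(dilution * n))
            recoveries: list[float] = []
            for _ in range(reps):
                keep = rng.choice(n, size=k, replace=False)
                sampled = {ids[i] for i in keep}
                restricted = {
                    (a, b) for a, b in p_full
                    if a in sampled and b in sampled
                }
                if not restricted:
                    n_skipped += 1
                    continue
                sub = collection.subset(sampled)
                p_rep = co_cluster_pairs(
                    build_superpaths(sub, t1=t1, t2=t2, **cluster_kwargs)
                )
                recoveries.append(
                    len(p_rep & restricted) / len(restricted)
                )
            rows.append(
                StabilityRow(t2=t2, dilution=dilution, recoveries=recoveries)
            )
    return StabilityResult(rows=rows, n_skipped=n_skipped)
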