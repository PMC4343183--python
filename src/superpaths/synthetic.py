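"""Synthetic pathway corpora with planted SuperPath structure.

Real pathway databases describe the same biological processes with
overlapping but idiosyncratic gene sets and correlated names.  The
generator emulates that: a set of disjoint base *modules* (the ground
truth) is drawn from a gene universe; each module is released as
several *variants* across pseudo-sources, where a variant keeps each
module gene with probability ``keep_rate`` and picks up background
genes at ``noise_rate``.  Variant names share a module-specific word
pool but carry source-specific decorations, so name similarity
correlates only imperfectly with gene content.  Unrelated noise
pathways are mixed in.  Pair-evidence tables (publication counts, PPI
scores) carry elevated signal for within-module gene pairs.

Everything is deterministic under the seed and regenerable from the
config echo stored on the truth object.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluation import PairEvidence
from .model import Pathway, PathwayCollection

_MODULE_WORDS = [
    "kinase", "receptor", "transport", "adhesion", "apoptosis", "cycle",
    "repair", "glycolysis", "synthesis", "immune", "axon", "matrix",
    "oxidative", "ribosome", "splicing", "secretion", "channel", "lipid",
    "hormone", "translation", "folding", "proteolysis", "migration",
    "polarity", "autophagy", "senescence", "clotting", "vision", "taste",
    "olfaction",
]
_DECORATIONS = ["signaling", "regulation", "pathway", "network", "cascade"]


@dataclass
class SyntheticTruth:
    """Planted structure: base modules, each pathway's parent module
    (None for noise and composite pathways), which module pair each
    composite pathway spans, and the full generator config echo."""

    modules: list[frozenset[str]]
    pathway_parent: dict[str, int | None]
    bridge_parents: dict[str, tuple[int, int]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def labels(self) -> dict[str, int]:
        """Integer cluster labels for external-index comparison; every
        noise pathway gets its own label."""
        out: dict[str, int] = {}
        next_noise = len(self.modules)
        for pid in sorted(self.pathway_parent):
            parent = self.pathway_parent[pid]
            if parent is None:
                out[pid] = next_noise
                next_noise += 1
            else:
                out[pid] = parent
        return out


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_collection(
    n_modules: int = 10,
    module_size_range: tuple[int, int] = (20, 60),
    n_sources: int = 4,
    variants_per_module: tuple[int, int] = (2, 4),
    keep_rate: float = 0.8,
    noise_rate: float = 0.05,
    n_noise_pathways: int = 10,
    n_bridge_pathways: int = 0,
    universe_size: int = 2000,
    seed: int = 0,
) -> tuple[PathwayCollection, SyntheticTruth]:
    """Draw a multi-source corpus with planted modules.

    Defaults model a desk-scale corpus: 10 disjoint modules of 20-60
    genes in a 2000-gene universe, 2-4 variants each spread over 4
    pseudo-sources, 80% gene retention, 5% background contamination
    and 10 unrelated noise pathways.

    ``n_bridge_pathways`` adds composite pathways — the full union of
    two planted modules of moderately different sizes, the way
    hierarchical sources publish parent pathways spanning related
    processes.  A composite's similarity to its larger module
    (J ~ 0.8r/(r+1) for size ratio r) exceeds that to the smaller one
    (J ~ 0.8/(r+1) ~ 0.3-0.4), so low upper cutoffs chain the two
    modules together through it while higher cutoffs keep them apart:
    the chaining regime a stability scan must detect.
    """
    for rate in (keep_rate, noise_rate):
        if not 0 <= rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
    lo, hi = module_size_range
    if lo < 2:
        raise ValueError("module sizes must be >= 2")
    if n_modules * hi > universe_size:
        raise ValueError(
            "universe too small for the requested disjoint modules"
        )
    rng = np.random.default_rng(seed)
    universe = _gene_names(universe_size)
    shuffled = list(rng.permutation(universe))

    modules: list[frozenset[str]] = []
    cursor = 0
    for _ in range(n_modules):
        size = int(rng.integers(lo, hi + 1))
        modules.append(frozenset(shuffled[cursor:cursor + size]))
        cursor += size
    background = shuffled[cursor:]

    pathways: list[Pathway] = []
    parent: dict[str, int | None] = {}
    vlo, vhi = variants_per_module
    for mi, module in enumerate(modules):
        module_genes = sorted(module)
        words = rng.choice(_MODULE_WORDS, size=2, replace=False)
        n_variants = int(rng.integers(vlo, vhi + 1))
        sources = rng.choice(n_sources, size=n_variants, replace=True)
        for vi in range(n_variants):
            keep = [g for g in module_genes if rng.random() < keep_rate]
            while len(keep) < 2:  # a variant never degenerates
                extra = module_genes[int(rng.integers(len(module_genes)))]
                if extra not in keep:
                    keep.append(extra)
            n_noise = rng.binomial(len(module_genes), noise_rate)
            if n_noise:
                picks = rng.choice(len(background), size=n_noise,
                                   replace=False)
                keep.extend(background[i] for i in picks)
            source = f"src{int(sources[vi])}"
            deco = _DECORATIONS[int(rng.integers(len(_DECORATIONS)))]
            pid = f"M{mi:02d}V{vi}"
            name = f"{' '.join(words)} {deco} {vi + 1}"
            pathways.append(Pathway(pid, source, name, frozenset(keep)))
            parent[pid] = mi
    for ni in range(n_noise_pathways):
        size = int(rng.integers(lo, hi + 1))
        picks = rng.choice(len(background), size=size, replace=False)
        genes = frozenset(background[i] for i in picks)
        source = f"src{int(rng.integers(n_sources))}"
        word = _MODULE_WORDS[int(rng.integers(len(_MODULE_WORDS)))]
        pid = f"N{ni:03d}"
        pathways.append(
            Pathway(pid, source, f"{word} noise set {ni}", genes)
        )
        parent[pid] = None

    bridge_parents: dict[str, tuple[int, int]] = {}
    for bi in range(n_bridge_pathways):
        # prefer module pairs with a size ratio in [1.1, 1.45]: the
        # composite then sits clearly closer to the larger module while
        # staying within core-edge reach of the smaller one
        pair = None
        for _ in range(100):
            a, b = (int(x) for x in rng.choice(n_modules, 2, replace=False))
            big, small = ((a, b) if len(modules[a]) >= len(modules[b])
                          else (b, a))
            r = len(modules[big]) / len(modules[small])
            if 1.1 <= r <= 1.45:
                pair = (big, small)
                break
        if pair is None:
            pair = (big, small)
        genes = modules[pair[0]] | modules[pair[1]]
        source = f"src{int(rng.integers(n_sources))}"
        pid = f"B{bi:02d}"
        pathways.append(
            Pathway(pid, source,
                    f"combined process {pair[0]} and {pair[1]}", genes)
        )
        parent[pid] = None
        bridge_parents[pid] = pair

    truth = SyntheticTruth(
        modules=modules,
        pathway_parent=parent,
        bridge_parents=bridge_parents,
        config=dict(
            n_modules=n_modules,
            module_size_range=tuple(module_size_range),
            n_sources=n_sources,
            variants_per_module=tuple(variants_per_module),
            keep_rate=keep_rate,
            noise_rate=noise_rate,
            n_noise_pathways=n_noise_pathways,
            n_bridge_pathways=n_bridge_pathways,
            universe_size=universe_size,
            seed=seed,
        ),
    )
    return PathwayCollection(pathways), truth


def regenerate(truth: SyntheticTruth) -> tuple[PathwayCollection, SyntheticTruth]:
    """Rebuild the corpus bit-for-bit from the config echo."""
    return generate_collection(**truth.config)


# --------------------------------------------------------- pair evidence


def _pair_rng(seed: int, a: str, b: str, salt: int) -> np.random.Generator:
    key = zlib.crc32(f"{min(a, b)}|{max(a, b)}".encode())
    return np.random.default_rng((seed, salt, key))


def generate_pair_evidence(
    truth: SyntheticTruth,
    background_rate: float = 2.0,
    signal_multiplier: float = 1.0,
    dispersion: float = 0.5,
    seed: int = 0,
) -> tuple[PairEvidence, PairEvidence]:
    """Publication-count and PPI-score evidence models.

    Counts follow a negative-binomial (over-dispersed, heavy-tailed)
    law with mean ``background_rate``, multiplied by
    ``signal_multiplier`` for gene pairs inside the same planted
    module; PPI scores are Beta-distributed in [0, 1] with a matching
    within-module upward shift.  Values are drawn lazily per pair
    from a hash-derived stream, so every gene pair has a well-defined,
    seed-deterministic value and, at ``signal_multiplier = 1``, all
    pairs are identically distributed (an exact null).
    """
    if signal_multiplier < 1:
        raise ValueError("signal_multiplier must be >= 1")
    gene_module: dict[str, int] = {}
    for mi, module in enumerate(truth.modules):
        for g in module:
            gene_module[g] = mi

    def within_module(pair: tuple[str, str]) -> bool:
        a, b = pair
        ma, mb = gene_module.get(a), gene_module.get(b)
        return ma is not None and ma == mb

    def pub_count(pair: tuple[str, str]) -> int:
        rng = _pair_rng(seed, *pair, salt=1)
        mean = background_rate * (
            signal_multiplier if within_module(pair) else 1.0
        )
        p = dispersion / (dispersion + mean)
        return int(rng.negative_binomial(dispersion, p))

    def ppi_score(pair: tuple[str, str]) -> float:
        rng = _pair_rng(seed, *pair, salt=2)
        a = 1.2 * (signal_multiplier if within_module(pair) else 1.0)
        return float(rng.beta(a, 8.0))

    publications = PairEvidence(kind="count", default=pub_count)
    ppi = PairEvidence(kind="score", default=ppi_score)
    return publications, ppi


def generate_query_sets(
    truth: SyntheticTruth,
    n_sets: int = 50,
    from_module_fraction: float = 0.8,
    size_range: tuple[int, int] = (10, 30),
    universe: Sequence[str] | None = None,
    seed: int = 0,
) -> list[frozenset[str]]:
    """Differential-expression-like query gene sets.

    Each query is anchored to one planted module (cycled); each of its
    genes comes from that module with probability
    ``from_module_fraction`` and from the rest of the universe
    otherwise.  With fraction 0 the queries are pure background.
    """
    if universe is None:
        universe = _gene_names(truth.config.get("universe_size", 2000))
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    queries: list[frozenset[str]] = []
    for qi in range(n_sets):
        module = sorted(truth.modules[qi % len(truth.modules)])
        others = [g for g in universe if g not in set(module)]
        size = int(rng.integers(lo, hi + 1))
        genes: set[str] = set()
        while len(genes) < size:
            if rng.random() < from_module_fraction:
                genes.add(module[int(rng.integers(len(module)))])
            else:
                genes.add(others[int(rng.integers(len(others)))])
        queries.append(frozenset(genes))
    return queries
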