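import numpy as np
import pytest

from superpaths.model import Pathway, PathwayCollection


@pytest.fixture
def tiny_collection() -> PathwayCollection:
    """Three small pathways from two sources with partial overlap."""
    return PathwayCollection(
        [
            Pathway("P1", "KEGG", "Oocyte meiosis", frozenset("ABC")),
            Pathway("P2", "KEGG", "Meiotic recombination", frozenset("BCD")),
            Pathway("P3", "Reactome", "Glycolysis", frozenset("XYZ")),
        ]
    )


def random_collection(
    seed: int, n: int = 10, universe: int = 30, min_size: int = 2,
    max_size: int = 10,
) -> PathwayCollection:
    """Small random corpus for oracle comparisons."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(universe)]
    pathways = []
    for i in range(n):
        size = int(rng.integers(min_size, max_size + 1))
        picks = rng.choice(universe, size=size, replace=False)
        pathways.append(
            Pathway(
                f"p{i}", f"s{int(rng.integers(3))}", f"set {i}",
                frozenset(genes[j] for j in picks),
            )
        )
    return PathwayCollection(pathways)
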