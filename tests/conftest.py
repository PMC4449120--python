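import numpy as np
import pytest

from lexevo.cognate import BinaryCharacterMatrix, DistanceMatrix, LexiconTable
from lexevo.phylo import TimeTree


@pytest.fixture
def toy_lexicon() -> LexiconTable:
    """2 variants x 2 meanings; variant2 lacks meaning m2 entirely."""
    return LexiconTable([
        ("v1", "m1", "hand", "A"),
        ("v1", "m2", "foot", "C"),
        ("v2", "m1", "mano", "B"),
    ])


@pytest.fixture
def toy_matrix() -> BinaryCharacterMatrix:
    """The binarized toy: columns (m1,A),(m1,B),(m2,C); v2 missing m2."""
    return BinaryCharacterMatrix(
        ["v1", "v2"],
        [("m1", "A"), ("m1", "B"), ("m2", "C")],
        np.array([[1, 0, 1], [0, 1, -1]], dtype=np.int8),
    )


@pytest.fixture
def three_taxon_tree() -> TimeTree:
    """((a:1000,b:1000):1500,c:2500) with explicit node ages."""
    return TimeTree(
        ["a", "b", "c"],
        parent=[3, 3, 4, 4, -1],
        children=[[], [], [], [0, 1], [3, 2]],
        age=[0.0, 0.0, 0.0, 1000.0, 2500.0],
    )


def quartet_distance_matrix() -> DistanceMatrix:
    """Additive metric of ((A:1,B:1):1,(C:1,D:1):1)."""
    d = np.array([[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float)
    return DistanceMatrix(["A", "B", "C", "D"], d)


def random_tree_distance_matrix(n: int, rng: np.random.Generator) -> tuple:
    """Random rooted tree with uniform branch lengths and its path metric."""
    import dendropy
    import random as _random

    taxa = [f"t{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        taxon_namespace=tns, rng=_random.Random(int(rng.integers(1 << 30))))
    for e in tree.edges():
        if e.length is not None:
            e.length = float(rng.uniform(0.1, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n, n))
    for i, ti in enumerate(tns):
        for j, tj in enumerate(tns):
            d[i, j] = pdm.distance(ti, tj)
    return DistanceMatrix(taxa, d), tree
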