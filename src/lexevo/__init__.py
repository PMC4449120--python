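"""lexevo: quantitative language-history analyses on binary cognate data.

Stages: cognate coding (:mod:`lexevo.cognate`), Bayesian phylogenetics
(:mod:`lexevo.phylo`), NeighborNet split networks
(:mod:`lexevo.neighbornet`), admixture clustering (:mod:`lexevo.admixture`),
geographic barriers (:mod:`lexevo.barrier`), isolation-by-barrier Mantel
tests (:mod:`lexevo.mantel`), a ground-truthed simulator
(:mod:`lexevo.synth`), and end-to-end orchestration
(:mod:`lexevo.pipeline`).
"""

from importlib import resources

from .cognate import (
    BinaryCharacterMatrix,
    DistanceMatrix,
    LexiconTable,
    binarize,
    hamming_distance,
    jaccard_distance,
    read_lexicon,
    read_nexus_characters,
    write_nexus_characters,
)
from .errors import (
    ConfigError,
    DataError,
    FormatError,
    GeometryError,
    LexevoError,
    NumericError,
)

__version__ = "0.1.0"


def korea_sites_path():
    """Path to the approximate 14-site coordinate fixture shipped with the
    package (hand-placed province centroids, marked synthetic)."""
    return resources.files("lexevo") / "data" / "korea_sites_approx.csv"
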