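import numpy as np
import pytest

from phylotrace.census import CensusMatrix, CharacterMatrix
from phylotrace.synth import (
    AccretionConfig,
    GeneratorConfig,
    generate_accretion_census,
    generate_census,
)
from phylotrace.trees import Phylogeny


@pytest.fixture
def quartet_matrix():
    """Single ordered character, states A=B=0, C=D=3."""
    return CharacterMatrix(
        taxa=list("ABCD"),
        characters=["c"],
        states=np.array([[0], [0], [3], [3]]),
        n_states=24,
    )


@pytest.fixture
def quartet_trees():
    good = Phylogeny.from_topology((("A", "B"), ("C", "D")), rooted=False)
    bad = Phylogeny.from_topology((("A", "C"), ("B", "D")), rooted=False)
    return good, bad


@pytest.fixture(scope="session")
def default_census():
    """Default four-group composition-mode census (16 taxa)."""
    return generate_census(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def accretion_census():
    """Accretion-mode census evolved on a known global tree."""
    return generate_accretion_census(AccretionConfig(seed=7))


@pytest.fixture
def tiny_census():
    return CensusMatrix(
        taxa=["t1", "t2"],
        groups={"t1": "A", "t2": "B"},
        fsf_ids=["f1", "f2"],
        abundance=np.array([[1, 0], [2, 3]]),
    )
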