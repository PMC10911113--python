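import numpy as np
import pytest

from cgdna.forcefield import ForceField
from cgdna.geometry import build_bdna_coordinates
from cgdna.topology import build_dna_topology

S1 = "GCGTCATACAGTGC"
S2 = "GCACTGTATGACGC"
SEQ32 = "ATACAAAGGTGCGAGGTTTCTATGCTCCCACG"


@pytest.fixture(scope="session")
def duplex2():
    return build_dna_topology(S1, "two_bead", duplex=True)


@pytest.fixture(scope="session")
def duplex3():
    return build_dna_topology(S1, "three_bead", duplex=True)


@pytest.fixture(scope="session")
def coords2(duplex2):
    return build_bdna_coordinates(duplex2)


@pytest.fixture(scope="session")
def coords3(duplex3):
    return build_bdna_coordinates(duplex3)


@pytest.fixture(scope="session")
def ff2(duplex2):
    return ForceField(duplex2)


@pytest.fixture(scope="session")
def ff3(duplex3):
    return ForceField(duplex3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
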