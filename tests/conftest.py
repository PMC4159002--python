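import pytest

from rnaqs.energy import EnergyParams
from rnaqs.folding import NussinovFoldEngine

# A 50-nt unit of replication under the fallback engine, designed so that
# base-pair maximization reproduces the intended phenotype exactly:
# C-only dangling ends (five C's score exactly the -0.75 recognition
# threshold), A/U-only stems forming the catalytic two-hairpin multiloop,
# C spacers in all loops.  The reverse complement has G tails and mirrored
# A/U stems, so both strands fold cleanly and the genotype is a unit of
# replication with both strands catalytic.
FALLBACK_UNIT = "CCCCCUUUUUUUAACCCCUUAACCAAUUCCCCAAUUCCAAAAACCCCCCC"


@pytest.fixture(scope="session")
def fallback_engine():
    return NussinovFoldEngine()


@pytest.fixture(scope="session")
def vienna_engine():
    from rnaqs.folding import ViennaFoldEngine

    return ViennaFoldEngine()


@pytest.fixture(scope="session")
def energy():
    return EnergyParams()
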