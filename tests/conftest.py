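import numpy as np
import pytest

from loopcsa.fixtures import ScaffoldSpec, make_scaffold
from loopcsa.structure import (LoopDefinition, build_chain_from_torsions,
                               torsions_from_coords)


@pytest.fixture(scope="session")
def chain20():
    """A 20-residue chain covering many residue types, random coil."""
    rng = np.random.default_rng(101)
    seq = "AERLKSVTWQDFNMHYGAILPC"
    phi = rng.uniform(-150, -50, len(seq))
    psi = rng.uniform(-60, 160, len(seq))
    return build_chain_from_torsions(seq, phi, psi)


@pytest.fixture(scope="session")
def loop8():
    return LoopDefinition("A", 6, 13)


@pytest.fixture(scope="session")
def native_torsions(chain20, loop8):
    return torsions_from_coords(chain20, loop8)


@pytest.fixture(scope="session")
def scaffold():
    return make_scaffold(ScaffoldSpec(rng_seed=3))


@pytest.fixture(scope="session")
def scaffold_loop():
    return ScaffoldSpec(rng_seed=3).loop
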