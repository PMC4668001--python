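import numpy as np
import pytest

from bcct.structure import read_structure, read_trajectory
from bcct.synthetic import (build_landscape, simulate_trajectory,
                            write_toy_structure)


@pytest.fixture(scope="session")
def wt_model():
    return build_landscape("WT")


@pytest.fixture(scope="session")
def wt_traj(wt_model):
    """Shared 20k-frame WT trajectory with water counts."""
    return simulate_trajectory(wt_model, 20000, seed=2025)


@pytest.fixture(scope="session")
def toy_pdb():
    """(pdb_text, truth) for a 3-model toy structure with jitter."""
    return write_toy_structure(n_frames=3, seed=7, jitter=0.02)


@pytest.fixture(scope="session")
def toy_structure(toy_pdb):
    return read_structure(toy_pdb[0])


@pytest.fixture(scope="session")
def toy_traj(toy_structure):
    return read_trajectory(toy_structure)


@pytest.fixture(scope="session")
def reference_traj():
    """Single-model synthetic reference structure (crystal geometry)."""
    from bcct.synthetic import write_reference_structure

    pdb_text, truth = write_reference_structure()
    structure = read_structure(pdb_text)
    return read_trajectory(structure), truth
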