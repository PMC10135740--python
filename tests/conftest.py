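import numpy as np
import pandas as pd
import pytest

from trrdf import ParticleGroups, RadialGrid, Trajectory
from trrdf.fixtures import generate_ideal_gas, generate_two_particle


@pytest.fixture
def small_gas() -> Trajectory:
    """8 ideal-gas particles, 4 frames, 4 nm cube — brute-forceable."""
    return generate_ideal_gas(8, 4, 4.0, seed=42)


@pytest.fixture
def small_gas_groups(small_gas) -> ParticleGroups:
    idx = np.arange(small_gas.n_atoms)
    return ParticleGroups({"all": idx}, {"all": idx})


@pytest.fixture
def pair_fixture() -> Trajectory:
    """One reference + one target at 0.5 nm in an 8 nm^3 cube, 1 frame."""
    return generate_two_particle([0.5], cell=2.0)


@pytest.fixture
def coarse_grid() -> RadialGrid:
    return RadialGrid(r_min=0.0, r_max=1.0, n_bins=10)


@pytest.fixture
def tripeptide_topology() -> pd.DataFrame:
    """Three residues (ALA, GLY, LYS) with a couple of ions appended."""
    rows = [
        # name, element, resname, resid, chain
        ("N", "N", "ALA", 0, 0),
        ("CA", "C", "ALA", 0, 0),
        ("CB", "C", "ALA", 0, 0),
        ("C", "C", "ALA", 0, 0),
        ("O", "O", "ALA", 0, 0),
        ("N", "N", "GLY", 1, 0),
        ("CA", "C", "GLY", 1, 0),
        ("C", "C", "GLY", 1, 0),
        ("O", "O", "GLY", 1, 0),
        ("N", "N", "LYS", 2, 0),
        ("CA", "C", "LYS", 2, 0),
        ("CB", "C", "LYS", 2, 0),
        ("CG", "C", "LYS", 2, 0),
        ("CD", "C", "LYS", 2, 0),
        ("CE", "C", "LYS", 2, 0),
        ("NZ", "N", "LYS", 2, 0),
        ("NA", "Na", "NA", 3, 1),
        ("CL", "Cl", "CL", 4, 1),
    ]
    return pd.DataFrame(rows, columns=["name", "element", "resname", "resid", "chain"])
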