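import numpy as np
import pytest

from solvmut.rism_backend import solve_1d_rism
from solvmut.solvation_core import (
    SoluteSite,
    ThermodynamicState,
    mild_solvent,
    water_model,
)
from solvmut.synthetic_data import benchmark_suite


@pytest.fixture(scope="session")
def state():
    return ThermodynamicState()


@pytest.fixture(scope="session")
def water():
    return water_model()


@pytest.fixture(scope="session")
def mild():
    return mild_solvent()


@pytest.fixture(scope="session")
def dressed_sus(water, state):
    """Dressed water susceptibility from the 1-D RISM/KH solve (shared:
    the solve takes ~half a minute)."""
    return solve_1d_rism(water, state, closure="kh", damping=0.2,
                         max_iter=5000)


@pytest.fixture(scope="session")
def benches():
    return benchmark_suite(seed=1)


@pytest.fixture
def single_ion_site():
    return [SoluteSite(position=[0.0, 0.0, 0.0], charge=1.0, sigma=3.0,
                       epsilon=0.15, residue_index=0)]


def make_peptide():
    """Small all-atom-style peptide fixture used by I/O and geometry tests:
    5 residues, 38 heavy atoms, arbitrary but fixed coordinates."""
    from solvmut.structure_io import Atom, Residue, StructureEnsemble

    rng = np.random.default_rng(1234)
    layout = [
        ("ASP", ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"]),
        ("LYS", ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"]),
        ("ALA", ["N", "CA", "C", "O", "CB"]),
        ("GLU", ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"]),
        ("GLY", ["N", "CA", "C", "O"]),
        ("SER", ["N", "CA", "C"]),  # truncated to reach 38 atoms
    ]
    residues, atoms, coords = [], [], []
    serial = 1
    for i, (aa, names) in enumerate(layout):
        residues.append(Residue(chain_id="A", seq_number=i + 1, aa_type=aa))
        base = np.array([3.8 * i, 0.0, 0.0])
        for j, name in enumerate(names):
            el = name[0]
            atoms.append(Atom(serial=serial, name=name, element=el,
                              residue_index=i))
            coords.append(base + rng.normal(scale=1.2, size=3))
            serial += 1
    assert len(atoms) == 38
    return StructureEnsemble(atoms=atoms, residues=residues,
                             frames=[np.array(coords)])


@pytest.fixture
def peptide():
    return make_peptide()
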