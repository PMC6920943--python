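import numpy as np
import pytest

from surfdyn import (
    Atom,
    MolecularSystem,
    Residue,
    SyntheticSpec,
    Trajectory,
    simulate_bound_ensemble,
    simulate_unbound_ensemble,
)
from surfdyn.synthetic import max_sasa_table

# Small-scale study conditions reused across detection tests: 3 replicates
# of 100 frames are plenty for the planted 10-point effects at sigma=0.1.
SMALL = dict(n_frames=100, n_replicates=3, seed=7)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(**SMALL)


@pytest.fixture(scope="session")
def small_unbound(small_spec):
    return simulate_unbound_ensemble(small_spec)


@pytest.fixture(scope="session")
def small_bound(small_spec):
    return simulate_bound_ensemble(small_spec)


@pytest.fixture(scope="session")
def small_table(small_spec):
    return max_sasa_table(small_spec)


def make_two_chain_system(n_a: int = 10, n_b: int = 4) -> MolecularSystem:
    """Chain A: n_a residues with CA+CB beads; chain B: n_b single-CA residues."""
    atoms, residues = [], []
    idx = 0
    for i in range(n_a):
        key = f"A:{i + 1}"
        members = []
        for name in ("CA", "CB"):
            atoms.append(Atom(idx, name, "C", key, 1.70, 12.011))
            members.append(idx)
            idx += 1
        residues.append(Residue(key, "ALA", tuple(members)))
    for i in range(n_b):
        key = f"B:{i + 1}"
        atoms.append(Atom(idx, "CA", "C", key, 1.70, 12.011))
        residues.append(Residue(key, "GLY", (idx,)))
        idx += 1
    return MolecularSystem(tuple(atoms), tuple(residues), name="duo")


@pytest.fixture
def duo_system() -> MolecularSystem:
    return make_two_chain_system()


def line_trajectory(system: MolecularSystem, n_frames: int = 3) -> Trajectory:
    """Atoms spread on a line, identical in every frame."""
    n = system.n_atoms
    coords = np.zeros((n_frames, n, 3))
    coords[:, :, 0] = 5.0 * np.arange(n)[None, :]
    coords[:, :, 1] = 0.1 * np.arange(n)[None, :] ** 2  # break collinearity
    return Trajectory(system, coords, np.arange(n_frames, dtype=float))
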