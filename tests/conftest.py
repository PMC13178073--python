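import numpy as np
import pytest
from hypothesis import settings

from posedelta.core import AtomRecord, MolecularSystem, SnapshotEnsemble

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_atom(serial, position, name="X", residue_id=1, residue_name="RES",
              chain="A", charge=0.0, gb_radius=1.5, lj_rmin_half=1.7,
              lj_epsilon=0.1, gb_screen=0.8):
    return AtomRecord(serial=serial, name=name, residue_id=residue_id,
                      residue_name=residue_name, chain=chain,
                      position=np.asarray(position, dtype=float), charge=charge,
                      gb_radius=gb_radius, lj_rmin_half=lj_rmin_half,
                      lj_epsilon=lj_epsilon, gb_screen=gb_screen)


def dimer_system(r, q1=0.0, q2=0.0, eps1=0.1, eps2=0.1, rmin_half1=1.7,
                 rmin_half2=1.7):
    """One receptor atom at origin, one ligand atom at distance r on x."""
    atoms = [
        make_atom(1, [0, 0, 0], charge=q1, lj_epsilon=eps1, lj_rmin_half=rmin_half1,
                  residue_name="REC"),
        make_atom(2, [r, 0, 0], charge=q2, lj_epsilon=eps2, lj_rmin_half=rmin_half2,
                  residue_id=2, residue_name="LIG"),
    ]
    return MolecularSystem(atoms, ligand_mask={2})


def random_small_system(rng, n_receptor=12, n_ligand=5):
    """Well-separated random system for brute-force energy oracles."""
    atoms = []
    serial = 1
    placed = []
    while len(placed) < n_receptor + n_ligand:
        candidate = rng.uniform(-6, 6, size=3)
        if all(np.linalg.norm(candidate - p) > 2.0 for p in placed):
            placed.append(candidate)
    for k, pos in enumerate(placed):
        is_lig = k >= n_receptor
        atoms.append(make_atom(
            serial, pos, charge=rng.uniform(-0.5, 0.5),
            residue_id=(100 if is_lig else 1 + k // 4),
            residue_name=("LIG" if is_lig else "REC"),
            lj_epsilon=rng.uniform(0.05, 0.2),
            lj_rmin_half=rng.uniform(1.4, 2.0),
            gb_radius=rng.uniform(1.3, 2.2),
        ))
        serial += 1
    lig = {a.serial for a in atoms if a.residue_name == "LIG"}
    return MolecularSystem(atoms, ligand_mask=lig)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_system(rng):
    return random_small_system(rng)


@pytest.fixture
def small_ensemble(small_system, rng):
    base = small_system.reference_positions
    frames = base[None] + rng.normal(0, 0.05, size=(4, small_system.n_atoms, 3))
    return SnapshotEnsemble(system=small_system, frames=frames)
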