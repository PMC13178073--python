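"""Domain types: atoms, systems, snapshot ensembles, regions, ligand graphs.

A :class:`MolecularSystem` fixes the atom partition (receptor vs ligand) and
all per-atom parameters; a :class:`SnapshotEnsemble` pairs one system with an
ordered stack of coordinate frames. Energetic routines consume the cached
numpy views exposed by the system so per-frame work is fully vectorised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_GB_SCREEN
from .errors import TopologyError


@dataclass
class AtomRecord:
    """One atom with coordinates-independent parameters.

    Positions are stored per frame in the ensemble; the ``position`` here is
    the reference (first-seen) coordinate from the input file.
    """

    serial: int
    name: str
    residue_id: int
    residue_name: str
    chain: str
    position: np.ndarray  # (3,) Angstrom
    charge: float = 0.0  # e
    gb_radius: float = 1.5  # intrinsic Born radius, A
    lj_rmin_half: float = 1.7  # A
    lj_epsilon: float = 0.1  # kcal/mol
    gb_screen: float = DEFAULT_GB_SCREEN

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise TopologyError(
                f"atom {self.serial} ({self.name}): position must be a finite 3-vector"
            )
        if not self.gb_radius > 0:
            raise TopologyError(
                f"atom {self.serial} ({self.name}): gb_radius must be > 0, got {self.gb_radius}"
            )
        if self.lj_epsilon < 0:
            raise TopologyError(
                f"atom {self.serial} ({self.name}): lj_epsilon must be >= 0"
            )


class MolecularSystem:
    """Ordered atom list plus a disjoint receptor/ligand partition.

    The two masks are sets of atom serials. They must be disjoint and
    together cover every atom; one mask may be empty only for
    single-species (solvation-only) systems.
    """

    def __init__(
        self,
        atoms: list[AtomRecord],
        ligand_mask: set[int],
        receptor_mask: set[int] | None = None,
    ):
        if not atoms:
            raise TopologyError("system must contain at least one atom")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise TopologyError("duplicate atom serials")
        all_serials = set(serials)
        ligand_mask = set(ligand_mask)
        if receptor_mask is None:
            receptor_mask = all_serials - ligand_mask
        receptor_mask = set(receptor_mask)
        if ligand_mask & receptor_mask:
            raise TopologyError("ligand and receptor masks overlap")
        if (ligand_mask | receptor_mask) != all_serials:
            missing = sorted(all_serials - (ligand_mask | receptor_mask))
            raise TopologyError(f"masks do not cover all atoms; missing serials {missing}")
        self.atoms = list(atoms)
        self.ligand_mask = ligand_mask
        self.receptor_mask = receptor_mask
        self._index_of = {s: i for i, s in enumerate(serials)}
        self._cache: dict[str, np.ndarray] = {}

    # -- cached per-atom arrays -------------------------------------------

    def _arr(self, key: str, getter) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = np.asarray([getter(a) for a in self.atoms])
        return self._cache[key]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def serials(self) -> np.ndarray:
        return self._arr("serials", lambda a: a.serial)

    @property
    def charges(self) -> np.ndarray:
        return self._arr("charges", lambda a: a.charge)

    @property
    def gb_radii(self) -> np.ndarray:
        return self._arr("gb_radii", lambda a: a.gb_radius)

    @property
    def gb_screens(self) -> np.ndarray:
        return self._arr("gb_screens", lambda a: a.gb_screen)

    @property
    def lj_rmin_half(self) -> np.ndarray:
        return self._arr("lj_rmin_half", lambda a: a.lj_rmin_half)

    @property
    def lj_epsilon(self) -> np.ndarray:
        return self._arr("lj_epsilon", lambda a: a.lj_epsilon)

    @property
    def residue_ids(self) -> np.ndarray:
        return self._arr("residue_ids", lambda a: a.residue_id)

    @property
    def reference_positions(self) -> np.ndarray:
        return self._arr("positions", lambda a: a.position).reshape(-1, 3)

    @property
    def ligand_indices(self) -> np.ndarray:
        if "lig_idx" not in self._cache:
            self._cache["lig_idx"] = np.asarray(
                [i for i, a in enumerate(self.atoms) if a.serial in self.ligand_mask],
                dtype=int,
            )
        return self._cache["lig_idx"]

    @property
    def receptor_indices(self) -> np.ndarray:
        if "rec_idx" not in self._cache:
            self._cache["rec_idx"] = np.asarray(
                [i for i, a in enumerate(self.atoms) if a.serial in self.receptor_mask],
                dtype=int,
            )
        return self._cache["rec_idx"]

    def index_of(self, serial: int) -> int:
        return self._index_of[serial]

    def invalidate_cache(self) -> None:
        """Call after mutating atom parameters in place."""
        self._cache.clear()

    def subsystem(self, indices: np.ndarray, ligand: bool = False) -> "MolecularSystem":
        """Single-species subsystem (for solvation-only evaluations)."""
        atoms = [self.atoms[i] for i in np.asarray(indices, dtype=int)]
        serials = {a.serial for a in atoms}
        if ligand:
            return MolecularSystem(atoms, ligand_mask=serials, receptor_mask=set())
        return MolecularSystem(atoms, ligand_mask=set(), receptor_mask=serials)


@dataclass
class SnapshotEnsemble:
    """Ordered coordinate frames over a fixed molecular system."""

    system: MolecularSystem
    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    frame_labels: np.ndarray | None = None  # optional times, ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise TopologyError("ensemble needs >= 1 frame of shape (n_atoms, 3)")
        if self.frames.shape[1:] != (self.system.n_atoms, 3):
            raise TopologyError(
                f"frame shape {self.frames.shape[1:]} does not match system "
                f"({self.system.n_atoms} atoms)"
            )
        if self.frame_labels is not None:
            self.frame_labels = np.asarray(self.frame_labels, dtype=float)
            if self.frame_labels.shape != (self.n_frames,):
                raise TopologyError("frame_labels length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass(frozen=True)
class RegionDefinition:
    """A labelled inclusive residue interval, e.g. helix H12."""

    label: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.last_residue < self.first_residue:
            raise TopologyError(
                f"region {self.label!r}: empty residue range "
                f"[{self.first_residue}, {self.last_residue}]"
            )

    def contains(self, residue_id: int) -> bool:
        return self.first_residue <= residue_id <= self.last_residue


# -- ligand graphs --------------------------------------------------------


@dataclass(frozen=True)
class GraphAtom:
    atomic_number: int
    formal_charge: int
    n_hydrogens: int  # total attached H (explicit + implicit)
    in_ring: bool


@dataclass(frozen=True)
class GraphBond:
    i: int
    j: int
    order: float  # 1, 2, 3 or 1.5 (aromatic)


class LigandGraph:
    """Small-molecule graph: the substrate for circular fingerprints."""

    ALLOWED_ORDERS = (1.0, 1.5, 2.0, 3.0)

    def __init__(self, atoms: list[GraphAtom], bonds: list[GraphBond]):
        self.atoms = list(atoms)
        self.bonds = list(bonds)
        n = len(atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise TopologyError(f"bond ({b.i},{b.j}) references invalid atoms")
            if b.order not in self.ALLOWED_ORDERS:
                raise TopologyError(f"bond order {b.order} not in {{1,2,3,aromatic}}")
        self.neighbors: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for b in self.bonds:
            self.neighbors[b.i].append((b.j, b.order))
            self.neighbors[b.j].append((b.i, b.order))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def is_connected(self) -> bool:
        if not self.atoms:
            return False
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v, _ in self.neighbors[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == self.n_atoms


def net_charge(system: MolecularSystem) -> float:
    """Sum of partial charges, e."""
    return float(np.sum(system.charges))


def pairwise_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All distances between two coordinate sets, (len(a), len(b))."""
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
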