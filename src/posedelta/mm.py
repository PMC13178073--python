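"""Intermolecular molecular-mechanics interaction energies.

Under the single-trajectory MM-GBSA convention the bonded and intramolecular
nonbonded terms of complex, receptor and ligand cancel exactly, so the
gas-phase interaction energy reduces to the receptor-ligand Coulomb and
Lennard-Jones sums evaluated on each complex frame. No distance cutoff is
applied: the rescored systems are finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_CONSTANT, DEFAULT_EPS_IN
from .core import MolecularSystem, SnapshotEnsemble, pairwise_distances
from .errors import GeometryError, TopologyError

_MIN_DISTANCE = 1e-6  # A; closer pairs are treated as coincident


@dataclass(frozen=True)
class FrameInteraction:
    """Receptor-ligand interaction energy of one frame (kcal/mol)."""

    e_ele: float
    e_vdw: float

    @property
    def e_int(self) -> float:
        return self.e_ele + self.e_vdw


@dataclass(frozen=True)
class ResidueContribution:
    """Ensemble-averaged per-residue interaction energy with the ligand."""

    residue_id: int
    ele: float
    vdw: float
    ele_sd: float = 0.0
    vdw_sd: float = 0.0


def _masked_distances(system: MolecularSystem, frame: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rec, lig = system.receptor_indices, system.ligand_indices
    if rec.size == 0 or lig.size == 0:
        raise TopologyError("receptor and ligand masks must both be nonempty")
    frame = np.asarray(frame, dtype=float)
    r = pairwise_distances(frame[rec], frame[lig])
    if np.any(r < _MIN_DISTANCE):
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise GeometryError(
            f"coincident atoms: serial {system.serials[rec[i]]} and "
            f"serial {system.serials[lig[j]]} at r={r[i, j]:.2e} A"
        )
    return rec, lig, r


def coulomb_interaction(system: MolecularSystem, frame: np.ndarray,
                        dielectric: float = DEFAULT_EPS_IN) -> float:
    """Receptor-ligand Coulomb energy, kcal/mol."""
    if not dielectric > 0:
        raise ValueError(f"dielectric must be > 0, got {dielectric}")
    rec, lig, r = _masked_distances(system, frame)
    q = system.charges
    return float(COULOMB_CONSTANT / dielectric * np.sum(np.outer(q[rec], q[lig]) / r))


def lj_interaction(system: MolecularSystem, frame: np.ndarray) -> float:
    """Receptor-ligand 12-6 Lennard-Jones energy with Lorentz-Berthelot
    combining (rmin/2 additive, epsilon geometric), kcal/mol."""
    rec, lig, r = _masked_distances(system, frame)
    eps = np.sqrt(np.outer(system.lj_epsilon[rec], system.lj_epsilon[lig]))
    rmin = system.lj_rmin_half[rec][:, None] + system.lj_rmin_half[lig][None, :]
    x6 = (rmin / r) ** 6
    return float(np.sum(eps * (x6 * x6 - 2.0 * x6)))


def frame_interaction(system: MolecularSystem, frame: np.ndarray,
                      dielectric: float = DEFAULT_EPS_IN) -> FrameInteraction:
    return FrameInteraction(
        e_ele=coulomb_interaction(system, frame, dielectric),
        e_vdw=lj_interaction(system, frame),
    )


def ensemble_interactions(ensemble: SnapshotEnsemble,
                          dielectric: float = DEFAULT_EPS_IN) -> list[FrameInteraction]:
    """Per-frame interaction energies for every frame of the ensemble."""
    return [frame_interaction(ensemble.system, f, dielectric) for f in ensemble.frames]


def per_residue_decomposition(system: MolecularSystem, ensemble: SnapshotEnsemble,
                              dielectric: float = DEFAULT_EPS_IN) -> list[ResidueContribution]:
    """Decompose the receptor-ligand interaction by receptor residue.

    Each receptor residue's contribution is the sum over its atom pairs with
    the ligand; summed over residues it reproduces the frame totals exactly.
    Means and standard deviations are taken across frames.
    """
    rec, lig = system.receptor_indices, system.ligand_indices
    if rec.size == 0 or lig.size == 0:
        raise TopologyError("receptor and ligand masks must both be nonempty")
    res_ids = system.residue_ids[rec]
    unique_res, inverse = np.unique(res_ids, return_inverse=True)
    q = system.charges
    eps = np.sqrt(np.outer(system.lj_epsilon[rec], system.lj_epsilon[lig]))
    rmin = system.lj_rmin_half[rec][:, None] + system.lj_rmin_half[lig][None, :]
    qq = np.outer(q[rec], q[lig])

    ele_frames = np.empty((ensemble.n_frames, unique_res.size))
    vdw_frames = np.empty_like(ele_frames)
    for k, frame in enumerate(ensemble.frames):
        _, _, r = _masked_distances(system, frame)
        ele_atom = COULOMB_CONSTANT / dielectric * np.sum(qq / r, axis=1)
        x6 = (rmin / r) ** 6
        vdw_atom = np.sum(eps * (x6 * x6 - 2.0 * x6), axis=1)
        ele_frames[k] = np.bincount(inverse, weights=ele_atom, minlength=unique_res.size)
        vdw_frames[k] = np.bincount(inverse, weights=vdw_atom, minlength=unique_res.size)

    return [
        ResidueContribution(
            residue_id=int(rid),
            ele=float(np.mean(ele_frames[:, k])),
            vdw=float(np.mean(vdw_frames[:, k])),
            ele_sd=float(np.std(ele_frames[:, k], ddof=0)),
            vdw_sd=float(np.std(vdw_frames[:, k], ddof=0)),
        )
        for k, rid in enumerate(unique_res)
    ]
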