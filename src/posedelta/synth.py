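"""Synthetic inputs with planted ground truth.

Three generators cover the pipeline's input surface:

* ``make_host_guest`` — a toy ring-shaped "receptor" (15 four-atom residues
  on a circle) plus a 10-atom charged guest, posed twice: pose A sits in
  the ring pocket with both Lennard-Jones and electrostatic
  complementarity (three pocket residues carry excess negative charge
  facing the cationic guest), pose B docks shallowly at the uncharged rim.
  The planted energetic ordering (A below B) is what pose inference must
  recover. Frames are the rigid pose plus isotropic Gaussian jitter.
* ``make_gaussian_energy_traj`` — i.i.d. normal interaction-energy samples
  for exercising the interaction-entropy estimator against its lognormal
  closed form.
* ``make_dose_response`` — 4PL plate data over the 1 pM - 100 uM dose range
  emitted as 520/495 channel pairs.

Every generator is a pure function of its spec: a fixed seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AtomRecord, MolecularSystem, SnapshotEnsemble
from .errors import PoseDeltaError
from .io import write_lj_sidecar, write_pdb_ensemble, write_pqr

N_RING_RESIDUES = 15
RING_RADIUS = 6.0  # A
POCKET_RESIDUES = (1, 2, 3)  # residue ids with excess negative charge
POCKET_EXTRA_CHARGE = -0.35  # e, added to the O atom
GUEST_RESIDUE_ID = 100
GUEST_RESNAME = "LIG"


@dataclass(frozen=True)
class FourPLParams:
    bottom: float
    top: float
    hill: float
    log_mid: float  # log10 M


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 1
    n_frames: int = 50
    jitter_sigma: float = 0.1  # A
    energy_sigma: float = 1.0  # kcal/mol
    pose_labels: tuple[str, str] = ("A", "B")
    dose_response_params: FourPLParams | None = None

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0 or self.energy_sigma < 0:
            raise PoseDeltaError("sigmas must be nonnegative")


@dataclass
class HostGuest:
    ensembles: dict[str, SnapshotEnsemble]
    planted_pose: str  # label of the pose constructed with the deeper well
    spec: SyntheticSpec


def _receptor_atoms() -> list[AtomRecord]:
    # residue template: a flat 4-atom unit; O carries the pocket charge
    template = {
        "N": (np.array([0.6, 0.0, 0.4]), -0.30, 1.55, 1.82, 0.17),
        "CA": (np.array([0.0, 0.0, 0.0]), 0.10, 1.70, 1.91, 0.11),
        "C": (np.array([-0.6, 0.0, 0.4]), 0.30, 1.70, 1.91, 0.09),
        "O": (np.array([0.0, 0.6, -0.4]), -0.10, 1.50, 1.66, 0.21),
    }
    atoms = []
    serial = 1
    for res in range(1, N_RING_RESIDUES + 1):
        angle = 2.0 * np.pi * (res - 1) / N_RING_RESIDUES
        center = RING_RADIUS * np.array([np.cos(angle), np.sin(angle), 0.0])
        rot = np.array(
            [[np.cos(angle), -np.sin(angle), 0.0],
             [np.sin(angle), np.cos(angle), 0.0],
             [0.0, 0.0, 1.0]]
        )
        for name, (offset, q, rgb, rmin, eps) in template.items():
            charge = q
            if name == "O" and res in POCKET_RESIDUES:
                charge += POCKET_EXTRA_CHARGE
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, residue_id=res, residue_name="GLY",
                    chain="A", position=center + rot @ offset, charge=charge,
                    gb_radius=rgb, lj_rmin_half=rmin, lj_epsilon=eps,
                )
            )
            serial += 1
    return atoms


def _guest_atoms(center: np.ndarray, first_serial: int) -> list[AtomRecord]:
    # 8-atom ring (radius 1.2 A) plus 2 axial caps; net charge +1 e
    positions = [
        center + 1.2 * np.array([np.cos(a), np.sin(a), 0.0])
        for a in np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False)
    ]
    positions += [center + np.array([0.0, 0.0, 1.0]), center + np.array([0.0, 0.0, -1.0])]
    charges = [0.25, 0.0, 0.25, 0.0, 0.25, 0.0, 0.25, 0.0, 0.0, 0.0]
    return [
        AtomRecord(
            serial=first_serial + i, name=f"G{i + 1}", residue_id=GUEST_RESIDUE_ID,
            residue_name=GUEST_RESNAME, chain="B", position=pos, charge=q,
            gb_radius=1.55, lj_rmin_half=1.85, lj_epsilon=0.12,
        )
        for i, (pos, q) in enumerate(zip(positions, charges))
    ]


def make_host_guest(spec: SyntheticSpec = SyntheticSpec()) -> HostGuest:
    """Two-pose host-guest snapshot ensembles with a planted pose ordering."""
    rng = np.random.default_rng(spec.seed)
    label_a, label_b = spec.pose_labels
    pose_centers = {
        label_a: np.zeros(3),  # pocket: surrounded by the ring, charged side
        label_b: np.array([-11.5, 0.0, 0.0]),  # shallow rim site, uncharged side
    }
    ensembles = {}
    for label, center in pose_centers.items():
        receptor = _receptor_atoms()
        guest = _guest_atoms(center, first_serial=len(receptor) + 1)
        atoms = receptor + guest
        system = MolecularSystem(atoms, ligand_mask={a.serial for a in guest})
        base = system.reference_positions
        jitter = rng.normal(0.0, spec.jitter_sigma,
                            size=(spec.n_frames, system.n_atoms, 3)) \
            if spec.jitter_sigma > 0 else np.zeros((spec.n_frames, system.n_atoms, 3))
        ensembles[label] = SnapshotEnsemble(system=system, frames=base[None, :, :] + jitter)
    return HostGuest(ensembles=ensembles, planted_pose=label_a, spec=spec)


def write_host_guest(hg: HostGuest, outdir: str | Path) -> dict[str, dict[str, Path]]:
    """Write each pose as PDB + PQR + LJ sidecar; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict[str, Path]] = {}
    for label, ens in hg.ensembles.items():
        stem = outdir / f"pose_{label}"
        p = {
            "pdb": stem.with_suffix(".pdb"),
            "pqr": stem.with_suffix(".pqr"),
            "sidecar": Path(f"{stem}_lj.json"),
        }
        write_pdb_ensemble(ens, p["pdb"])
        write_pqr(ens.system, p["pqr"])
        write_lj_sidecar(ens.system, p["sidecar"])
        paths[label] = p
    return paths


def make_gaussian_energy_traj(sigma: float, n: int, seed: int,
                              mean: float = -50.0) -> np.ndarray:
    """i.i.d. normal interaction-energy samples (kcal/mol)."""
    if sigma < 0 or n < 2:
        raise PoseDeltaError("need sigma >= 0 and n >= 2")
    rng = np.random.default_rng(seed)
    return mean + sigma * rng.standard_normal(n)


def make_dose_response(params: FourPLParams, noise_sd: float, n_reps: int,
                       seed: int, n_doses: int = 10,
                       dose_range_m: tuple[float, float] = (1e-12, 1e-4)) -> pd.DataFrame:
    """Synthetic plate table over a log-spaced dose series (default
    1 pM - 100 uM), as 520/495 channel pairs whose ratio is the 4PL response."""
    if noise_sd < 0 or n_reps < 1 or n_doses < 2:
        raise PoseDeltaError("invalid plate parameters")
    rng = np.random.default_rng(seed)
    doses = np.logspace(np.log10(dose_range_m[0]), np.log10(dose_range_m[1]), n_doses)
    rows = []
    em495 = 10000.0
    well = 0
    from .pharm import four_pl

    for dose in doses:
        clean = four_pl(np.asarray([dose]), params.bottom, params.top,
                        params.hill, params.log_mid)[0]
        for _ in range(n_reps):
            ratio = clean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {"well": f"W{well:03d}", "concentration": dose, "unit": "M",
                 "em520": ratio * em495, "em495": em495}
            )
            well += 1
    return pd.DataFrame(rows)
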