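"""Trajectory stability analytics: Kabsch superposition, RMSD series,
per-residue RMSF, ensemble SASA and region-level summaries.

Conventions: the backbone selection is atoms named N/CA/C/O; the binding
site is every receptor residue with any atom within a cutoff (default 5 A)
of the ligand in the reference frame; the reference is the first frame
unless an explicit structure is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import SASA_POINTS, SASA_PROBE
from .core import MolecularSystem, RegionDefinition, SnapshotEnsemble
from .errors import GeometryError, TopologyError
from .sasa import total_sasa

BACKBONE_NAMES = ("N", "CA", "C", "O")
SITE_RADIUS = 5.0  # A


@dataclass(frozen=True)
class MetricSeries:
    selection_label: str
    values: np.ndarray  # per-frame (RMSD, A; SASA, A^2) or per-residue (RMSF, A)
    kind: str  # "rmsd" | "rmsf" | "sasa"
    residue_ids: np.ndarray | None = None  # set for rmsf


# -- selections -----------------------------------------------------------

def select_backbone(system: MolecularSystem) -> np.ndarray:
    rec = set(system.receptor_mask)
    return np.asarray(
        [i for i, a in enumerate(system.atoms)
         if a.serial in rec and a.name in BACKBONE_NAMES],
        dtype=int,
    )


def select_ligand(system: MolecularSystem) -> np.ndarray:
    return system.ligand_indices


def select_residues(system: MolecularSystem, region: RegionDefinition) -> np.ndarray:
    return np.asarray(
        [i for i, a in enumerate(system.atoms) if region.contains(a.residue_id)],
        dtype=int,
    )


def select_binding_site(system: MolecularSystem, reference_frame: np.ndarray,
                        radius: float = SITE_RADIUS) -> np.ndarray:
    """Receptor atoms of residues having any atom within ``radius`` of the ligand."""
    ref = np.asarray(reference_frame, dtype=float)
    lig = ref[system.ligand_indices]
    rec = system.receptor_indices
    d = np.linalg.norm(ref[rec][:, None, :] - lig[None, :, :], axis=-1).min(axis=1)
    site_res = set(system.residue_ids[rec][d <= radius].tolist())
    return np.asarray(
        [i for i in rec if system.residue_ids[i] in site_res], dtype=int
    )


# -- superposition --------------------------------------------------------

def kabsch_superpose(mobile_frame: np.ndarray, reference_frame: np.ndarray,
                     fit_selection: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of a frame onto a reference.

    Returns (transformed full frame, rotation matrix, translation) where the
    proper rotation minimises the RMSD over ``fit_selection``.
    """
    mobile = np.asarray(mobile_frame, dtype=float)
    reference = np.asarray(reference_frame, dtype=float)
    sel = np.asarray(fit_selection, dtype=int)
    if sel.size < 3:
        raise GeometryError(f"superposition needs >= 3 fit atoms, got {sel.size}")
    x = mobile[sel]
    y = reference[sel]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) fit selection")
    cov = x0.T @ y0
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (mobile - xc) @ rot.T + yc
    return moved, rot, yc - rot @ xc


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(ensemble: SnapshotEnsemble, fit_selection: np.ndarray,
                measure_selection: np.ndarray | None = None,
                reference: np.ndarray | None = None,
                label: str = "rmsd") -> MetricSeries:
    """Per-frame RMSD after superposition on ``fit_selection``.

    Fitting on the backbone while measuring over the ligand reproduces the
    usual ligand-RMSD convention; by default the measured selection is the
    fit selection and the reference is the first frame.
    """
    fit_sel = np.asarray(fit_selection, dtype=int)
    measure_sel = fit_sel if measure_selection is None else np.asarray(measure_selection, dtype=int)
    if fit_sel.size == 0 or measure_sel.size == 0:
        raise TopologyError("empty selection")
    ref = ensemble.frames[0] if reference is None else np.asarray(reference, dtype=float)
    values = np.empty(ensemble.n_frames)
    for k, frame in enumerate(ensemble.frames):
        moved, _, _ = kabsch_superpose(frame, ref, fit_sel)
        values[k] = _rmsd(moved[measure_sel], ref[measure_sel])
    return MetricSeries(selection_label=label, values=values, kind="rmsd")


def rmsf_per_residue(ensemble: SnapshotEnsemble, fit_selection: np.ndarray,
                     label: str = "rmsf") -> MetricSeries:
    """Per-residue RMSF about the mean structure after superposition."""
    if ensemble.n_frames < 2:
        raise TopologyError("RMSF needs >= 2 frames")
    fit_sel = np.asarray(fit_selection, dtype=int)
    ref = ensemble.frames[0]
    aligned = np.empty_like(ensemble.frames)
    for k, frame in enumerate(ensemble.frames):
        aligned[k] = kabsch_superpose(frame, ref, fit_sel)[0]
    mean_structure = aligned.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((aligned - mean_structure) ** 2, axis=2), axis=0))
    res_ids = ensemble.system.residue_ids
    unique_res, inverse = np.unique(res_ids, return_inverse=True)
    sums = np.bincount(inverse, weights=per_atom, minlength=unique_res.size)
    counts = np.bincount(inverse, minlength=unique_res.size)
    return MetricSeries(
        selection_label=label,
        values=sums / counts,
        kind="rmsf",
        residue_ids=unique_res,
    )


def region_summary(rmsf: MetricSeries, regions: list[RegionDefinition]) -> dict[str, dict]:
    """Mean/max RMSF per labelled residue region (e.g. H11, H12)."""
    if rmsf.kind != "rmsf" or rmsf.residue_ids is None:
        raise TopologyError("region_summary expects a per-residue RMSF series")
    out = {}
    for region in regions:
        mask = np.asarray([region.contains(int(r)) for r in rmsf.residue_ids])
        if not mask.any():
            out[region.label] = {"n_residues": 0, "mean_rmsf": None, "max_rmsf": None}
            continue
        vals = rmsf.values[mask]
        out[region.label] = {
            "n_residues": int(mask.sum()),
            "mean_rmsf": float(vals.mean()),
            "max_rmsf": float(vals.max()),
        }
    return out


def ensemble_sasa(ensemble: SnapshotEnsemble, probe: float = SASA_PROBE,
                  points: int = SASA_POINTS, label: str = "complex_sasa") -> MetricSeries:
    """Per-frame total SASA of the complex, A^2."""
    values = np.asarray(
        [total_sasa(ensemble.system, f, probe=probe, n_points=points)
         for f in ensemble.frames]
    )
    return MetricSeries(selection_label=label, values=values, kind="sasa")
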