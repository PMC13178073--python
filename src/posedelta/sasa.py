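"""Shrake-Rupley solvent-accessible surface area.

Test points are placed on a deterministic golden-section spiral over each
atom's solvent-expanded sphere (radius + probe); a point survives if it lies
outside every other expanded sphere. Area per atom = exposed fraction times
the full sphere area.
"""

from __future__ import annotations

import numpy as np

from .core import MolecularSystem
from .constants import SASA_POINTS, SASA_PROBE


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (golden-section spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe: float = SASA_PROBE, n_points: int = SASA_POINTS) -> np.ndarray:
    """Per-atom SASA (A^2) for one frame."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    expanded = radii + probe
    unit = sphere_points(n_points)
    areas = np.empty(n)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    self_mask = np.eye(n, dtype=bool)
    for i in range(n):
        nbr = np.where((d[i] < expanded[i] + expanded) & ~self_mask[i])[0]
        if nbr.size == 0:
            areas[i] = 4.0 * np.pi * expanded[i] ** 2
            continue
        # |c_i + e_i*u_p - c_j|^2 = |m_j|^2 + e_i^2 + 2 e_i (u_p . m_j),
        # with m_j = c_i - c_j; one GEMM covers all points x neighbours
        m = coords[i] - coords[nbr]  # (k, 3)
        d2 = (m * m).sum(axis=1)[None, :] + expanded[i] ** 2 \
            + 2.0 * expanded[i] * (unit @ m.T)  # (npts, k)
        exposed = ~(d2 < expanded[nbr] ** 2).any(axis=1)
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed.sum() / n_points
    return areas


def total_sasa(system: MolecularSystem, frame: np.ndarray,
               probe: float = SASA_PROBE, n_points: int = SASA_POINTS) -> float:
    """Total SASA (A^2) of the system using intrinsic GB radii as atomic radii."""
    return float(np.sum(shrake_rupley(np.asarray(frame), system.gb_radii, probe, n_points)))
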