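"""Generalized-Born implicit solvation (OBC-II / igb=2) and the
SASA-proportional nonpolar term.

Effective Born radii come from Hawkins-Cramer-Truhlar pairwise descreening
with the Onufriev-Bashford-Case tanh rescaling, parameter set
alpha=0.8, beta=0, gamma=2.909125 (the igb=2 model). Intrinsic radii are
reduced by the conventional 0.09 A offset before descreening, so an isolated
atom's effective radius is its intrinsic radius minus 0.09 A.

The polar energy is the Still pairwise GB sum (self terms included); the
nonpolar term is gamma*SASA + b. The single-trajectory binding quantity
``delta_g_solv`` evaluates complex, receptor and ligand at the same complex
geometry, so internal coordinates cancel and only desolvation remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from .core import MolecularSystem, SnapshotEnsemble, pairwise_distances
from .errors import TopologyError
from .sasa import total_sasa


@dataclass(frozen=True)
class SolvationResult:
    g_polar: float
    g_nonpolar: float
    born_radii: np.ndarray

    @property
    def g_solv(self) -> float:
        return self.g_polar + self.g_nonpolar


@dataclass(frozen=True)
class GBConfig:
    eps_in: float = C.DEFAULT_EPS_IN
    eps_out: float = C.DEFAULT_EPS_OUT
    offset: float = C.GB_RADIUS_OFFSET
    alpha: float = C.OBC2_ALPHA
    beta: float = C.OBC2_BETA
    gamma: float = C.OBC2_GAMMA
    kappa: float = 0.0  # Debye screening, 1/A; 0 = no salt
    sasa_gamma: float = C.SASA_GAMMA
    sasa_beta: float = C.SASA_BETA
    sasa_probe: float = C.SASA_PROBE
    sasa_points: int = C.SASA_POINTS


def born_radii(system: MolecularSystem, frame: np.ndarray,
               config: GBConfig = GBConfig()) -> np.ndarray:
    """Effective Born radii (A) for one frame, OBC-II rescaled HCT."""
    coords = np.asarray(frame, dtype=float)
    rho = system.gb_radii
    if np.any(rho - config.offset <= 0):
        bad = system.serials[rho - config.offset <= 0]
        raise TopologyError(
            f"intrinsic radius <= offset ({config.offset} A) for serials {bad.tolist()}"
        )
    rho_t = rho - config.offset                      # offset-reduced radii
    s = system.gb_screens * rho_t                    # scaled descreening radii
    n = system.n_atoms
    if n == 1:
        integral = np.zeros(1)
    else:
        r = pairwise_distances(coords, coords)
        np.fill_diagonal(r, np.inf)
        rho_i = rho_t[:, None]
        s_j = s[None, :]
        U = r + s_j
        L = np.maximum(rho_i, np.abs(r - s_j))
        with np.errstate(divide="ignore", invalid="ignore"):
            H = 0.5 * (
                1.0 / L - 1.0 / U
                + (r / 4.0) * (1.0 / U**2 - 1.0 / L**2)
                + (1.0 / (2.0 * r)) * np.log(L / U)
                + (s_j**2 / (4.0 * r)) * (1.0 / L**2 - 1.0 / U**2)
            )
            # atom i buried inside atom j's scaled sphere
            buried = rho_i < (s_j - r)
            H = np.where(buried, H + (1.0 / rho_i - 1.0 / L), H)
        H = np.where(rho_i >= U, 0.0, H)
        H[~np.isfinite(H)] = 0.0
        integral = H.sum(axis=1)

    psi = integral * rho_t
    tanh_arg = config.alpha * psi - config.beta * psi**2 + config.gamma * psi**3
    inv_radius = 1.0 / rho_t - np.tanh(tanh_arg) / rho
    if np.any(inv_radius <= 0):
        bad = system.serials[inv_radius <= 0]
        raise TopologyError(f"nonpositive effective Born radius for serials {bad.tolist()}")
    return 1.0 / inv_radius


def gb_polar_energy(system: MolecularSystem, frame: np.ndarray,
                    config: GBConfig = GBConfig()) -> float:
    """Still-style pairwise GB polar solvation energy, kcal/mol."""
    if not (config.eps_out >= config.eps_in > 0):
        raise ValueError("require eps_out >= eps_in > 0")
    R = born_radii(system, frame, config)
    coords = np.asarray(frame, dtype=float)
    r2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    RR = np.outer(R, R)
    f_gb = np.sqrt(r2 + RR * np.exp(-r2 / (4.0 * RR)))
    q = system.charges
    qq = np.outer(q, q)
    if config.kappa > 0.0:
        contrast = 1.0 / config.eps_in - np.exp(-config.kappa * f_gb) / config.eps_out
    else:
        contrast = 1.0 / config.eps_in - 1.0 / config.eps_out
    return float(-C.COULOMB_CONSTANT / 2.0 * np.sum(contrast * qq / f_gb))


def sasa_nonpolar(system: MolecularSystem, frame: np.ndarray,
                  config: GBConfig = GBConfig()) -> float:
    """gamma*SASA + b nonpolar solvation term, kcal/mol."""
    if config.sasa_gamma == 0.0:
        return config.sasa_beta
    area = total_sasa(system, frame, probe=config.sasa_probe, n_points=config.sasa_points)
    return config.sasa_gamma * area + config.sasa_beta


def solvation_energy(system: MolecularSystem, frame: np.ndarray,
                     config: GBConfig = GBConfig()) -> SolvationResult:
    return SolvationResult(
        g_polar=gb_polar_energy(system, frame, config),
        g_nonpolar=sasa_nonpolar(system, frame, config),
        born_radii=born_radii(system, frame, config),
    )


def delta_g_solv(ensemble: SnapshotEnsemble, config: GBConfig = GBConfig()) -> np.ndarray:
    """Per-frame solvation contribution to binding, kcal/mol.

    Single-trajectory protocol: receptor and ligand are evaluated at the
    complex-frame geometry, so dG_solv = G(complex) - G(receptor) - G(ligand).
    """
    sys_ = ensemble.system
    rec_idx, lig_idx = sys_.receptor_indices, sys_.ligand_indices
    if rec_idx.size == 0 or lig_idx.size == 0:
        raise TopologyError("delta_g_solv needs nonempty receptor and ligand masks")
    rec_sys = sys_.subsystem(rec_idx)
    lig_sys = sys_.subsystem(lig_idx, ligand=True)
    out = np.empty(ensemble.n_frames)
    for k, frame in enumerate(ensemble.frames):
        g_cpx = solvation_energy(sys_, frame, config).g_solv
        g_rec = solvation_energy(rec_sys, frame[rec_idx], config).g_solv
        g_lig = solvation_energy(lig_sys, frame[lig_idx], config).g_solv
        out[k] = g_cpx - g_rec - g_lig
    return out
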