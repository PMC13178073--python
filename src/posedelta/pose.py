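"""Binding-mode inference: per-pose MM-GBSA + interaction entropy, assembled
into a ranked report.

For each replica the per-frame enthalpy is dH = E_int + dG_solv
(single-trajectory convention); the entropic term comes from the
interaction-entropy estimator on the same frames. The free energy follows
dG = dH - T*dS, and poses of a ligand are ranked by mean dG across
replicas (mean +- SD reported).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE
from .entropy import interaction_entropy
from .errors import PoseDeltaError, TopologyError
from .gb import GBConfig, delta_g_solv
from .mm import ensemble_interactions, per_residue_decomposition
from .core import SnapshotEnsemble

logger = logging.getLogger("posedelta")

_TOL = 1e-6


@dataclass(frozen=True)
class BindingEstimate:
    ligand_label: str
    pose_label: str
    e_ele_mean: float
    e_vdw_mean: float
    g_solv_mean: float
    t_delta_s: float  # signed: T*dS <= 0 (the entropic penalty -T*dS >= 0)
    delta_g_sd: float = 0.0
    n_replicas: int = 1
    entropy_converged: bool = True

    @property
    def e_int_mean(self) -> float:
        return self.e_ele_mean + self.e_vdw_mean

    @property
    def delta_h(self) -> float:
        return self.e_int_mean + self.g_solv_mean

    @property
    def delta_g(self) -> float:
        return self.delta_h - self.t_delta_s

    def __post_init__(self) -> None:
        if self.t_delta_s > _TOL:
            raise PoseDeltaError(
                f"t_delta_s must be <= 0 (got {self.t_delta_s}): the interaction-"
                "entropy term is an entropic penalty"
            )


def combine_energy_terms(e_int: float, g_solv: float, t_delta_s: float,
                         ligand_label: str = "", pose_label: str = "",
                         e_ele: float | None = None,
                         e_vdw: float | None = None) -> BindingEstimate:
    """Assemble a BindingEstimate from already-computed component values.

    This is the combination step of the MM-GBSA report: dH = E_int + dG_solv
    and dG = dH - T*dS, with the enthalpy split into its electrostatic and
    van der Waals parts when those are given.
    """
    if e_ele is None or e_vdw is None:
        e_ele, e_vdw = e_int, 0.0
    elif abs((e_ele + e_vdw) - e_int) > 1e-6:
        raise PoseDeltaError(
            f"e_ele + e_vdw = {e_ele + e_vdw} inconsistent with e_int = {e_int}"
        )
    return BindingEstimate(
        ligand_label=ligand_label, pose_label=pose_label,
        e_ele_mean=e_ele, e_vdw_mean=e_vdw, g_solv_mean=g_solv,
        t_delta_s=t_delta_s,
    )


@dataclass(frozen=True)
class PoseComparison:
    estimates: tuple[BindingEstimate, ...]
    preferred_pose: str
    margin: float  # kcal/mol, second-best minus best, >= 0
    tie: bool = False


def mmgbsa_estimate(ensembles_per_replica: list[SnapshotEnsemble],
                    ligand_label: str = "", pose_label: str = "",
                    gb_config: GBConfig = GBConfig(),
                    temperature: float = DEFAULT_TEMPERATURE) -> BindingEstimate:
    """MM-GBSA binding estimate from one or more replica ensembles.

    Per replica: per-frame E_int and dG_solv, averaged; -T*dS from the
    interaction-entropy estimator on that replica's E_int samples;
    dG by dG = dH - T*dS. Replicas are combined as mean +- SD.
    """
    if not ensembles_per_replica:
        raise PoseDeltaError("need at least one replica ensemble")
    n_frames = [e.n_frames for e in ensembles_per_replica]
    if any(n < 2 for n in n_frames):
        raise PoseDeltaError("each replica needs >= 2 frames")
    if len(set(n_frames)) > 1:
        logger.warning("replica frame counts differ: %s", n_frames)

    rep = {"e_ele": [], "e_vdw": [], "g_solv": [], "tds": [], "dg": [], "conv": []}
    for ens in ensembles_per_replica:
        inter = ensemble_interactions(ens, dielectric=gb_config.eps_in)
        e_int = np.asarray([fi.e_int for fi in inter])
        solv = delta_g_solv(ens, gb_config)
        est = interaction_entropy(e_int, temperature)
        dh = float(np.mean(e_int + solv))
        rep["e_ele"].append(float(np.mean([fi.e_ele for fi in inter])))
        rep["e_vdw"].append(float(np.mean([fi.e_vdw for fi in inter])))
        rep["g_solv"].append(float(np.mean(solv)))
        rep["tds"].append(-est.minus_t_delta_s)
        rep["dg"].append(dh - (-est.minus_t_delta_s))
        rep["conv"].append(est.converged)

    return BindingEstimate(
        ligand_label=ligand_label, pose_label=pose_label,
        e_ele_mean=float(np.mean(rep["e_ele"])),
        e_vdw_mean=float(np.mean(rep["e_vdw"])),
        g_solv_mean=float(np.mean(rep["g_solv"])),
        t_delta_s=float(np.mean(rep["tds"])),
        delta_g_sd=float(np.std(rep["dg"], ddof=0)),
        n_replicas=len(ensembles_per_replica),
        entropy_converged=all(rep["conv"]),
    )


def compare_poses(estimates: list[BindingEstimate]) -> PoseComparison:
    """Rank pose hypotheses of one ligand by dG (lowest = preferred).

    Ties on dG break toward the lower replica SD, then lexicographic pose
    label, and are flagged.
    """
    if len(estimates) < 2:
        raise PoseDeltaError("pose comparison needs >= 2 estimates")
    ligands = {e.ligand_label for e in estimates}
    if len(ligands) > 1:
        raise PoseDeltaError(f"mixed ligand labels in comparison: {sorted(ligands)}")
    ranked = sorted(estimates, key=lambda e: (e.delta_g, e.delta_g_sd, e.pose_label))
    margin = ranked[1].delta_g - ranked[0].delta_g
    return PoseComparison(
        estimates=tuple(ranked),
        preferred_pose=ranked[0].pose_label,
        margin=float(margin),
        tie=bool(abs(margin) <= _TOL),
    )


# -- orchestration --------------------------------------------------------

def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Full synthetic or file-based run: energies, entropy, metrics, pose
    comparison and per-residue decomposition as one JSON-able report.

    Config keys: either ``synthetic: {seed, n_frames, jitter_sigma}`` or
    ``poses: {label: {pdb, pqr, sidecar}}`` plus ``ligand_resname``;
    optional ``ligand_label``, ``eps_in``, ``temperature``, ``site_radius``.
    Every defaulted value is logged.
    """
    from . import metrics as tm
    from .io import read_lj_sidecar, read_pdb_ensemble, read_pqr_parameters
    from .synth import SyntheticSpec, make_host_guest

    stage = "configure"
    try:
        gb_config = GBConfig(eps_in=float(config.get("eps_in", GBConfig().eps_in)))
        temperature = float(config.get("temperature", DEFAULT_TEMPERATURE))
        ligand_label = config.get("ligand_label", "ligand")
        logger.info("pipeline defaults: eps_in=%s eps_out=%s T=%s K",
                    gb_config.eps_in, gb_config.eps_out, temperature)

        stage = "load"
        if "synthetic" in config:
            syn = config["synthetic"]
            spec = SyntheticSpec(
                seed=int(syn.get("seed", 1)),
                n_frames=int(syn.get("n_frames", 50)),
                jitter_sigma=float(syn.get("jitter_sigma", 0.1)),
            )
            ensembles = make_host_guest(spec).ensembles
        elif "poses" in config:
            ensembles = {}
            for label, paths in config["poses"].items():
                ens = read_pdb_ensemble(
                    paths["pdb"], ligand_resname=config.get("ligand_resname", "LIG")
                )
                read_pqr_parameters(paths["pqr"], ens.system)
                read_lj_sidecar(paths["sidecar"], ens.system)
                ensembles[label] = ens
        else:
            raise PoseDeltaError("config needs a 'synthetic' or 'poses' section")

        stage = "energetics"
        estimates = [
            mmgbsa_estimate([ens], ligand_label=ligand_label, pose_label=label,
                            gb_config=gb_config, temperature=temperature)
            for label, ens in ensembles.items()
        ]
        stage = "comparison"
        comparison = compare_poses(estimates)

        stage = "metrics"
        metrics_report = {}
        decomposition = {}
        for label, ens in ensembles.items():
            backbone = tm.select_backbone(ens.system)
            ligand = tm.select_ligand(ens.system)
            rmsd_bb = tm.rmsd_series(ens, backbone, label=f"{label}/backbone")
            rmsd_lig = tm.rmsd_series(ens, backbone, ligand, label=f"{label}/ligand")
            rmsf = tm.rmsf_per_residue(ens, backbone)
            sasa = tm.ensemble_sasa(ens)
            metrics_report[label] = {
                "rmsd_backbone_mean": float(rmsd_bb.values.mean()),
                "rmsd_ligand_mean": float(rmsd_lig.values.mean()),
                "rmsf_mean": float(rmsf.values.mean()),
                "sasa_mean": float(sasa.values.mean()),
                "sasa_sd": float(sasa.values.std(ddof=0)),
            }
            decomposition[label] = [
                asdict(rc) for rc in
                per_residue_decomposition(ens.system, ens, dielectric=gb_config.eps_in)
            ]
    except PoseDeltaError as exc:
        raise PoseDeltaError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "config": {"eps_in": gb_config.eps_in, "temperature": temperature},
        "estimates": [
            {**asdict(e), "e_int_mean": e.e_int_mean, "delta_h": e.delta_h,
             "delta_g": e.delta_g}
            for e in comparison.estimates
        ],
        "preferred_pose": comparison.preferred_pose,
        "margin": comparison.margin,
        "tie": comparison.tie,
        "metrics": metrics_report,
        "per_residue_decomposition": decomposition,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with (outdir / "report.json").open("w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        pd.DataFrame(report["estimates"]).to_csv(outdir / "estimates.csv", index=False)
        for label, rows in decomposition.items():
            pd.DataFrame(rows).to_csv(outdir / f"decomposition_{label}.csv", index=False)
    return report
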