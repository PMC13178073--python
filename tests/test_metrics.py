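"""Superposition, RMSD/RMSF, ensemble SASA and region reports."""

import numpy as np
import pytest

from posedelta import GeometryError, TopologyError
from posedelta.core import MolecularSystem, RegionDefinition, SnapshotEnsemble
from posedelta.metrics import (
    ensemble_sasa,
    kabsch_superpose,
    region_summary,
    rmsd_series,
    rmsf_per_residue,
    select_backbone,
    select_binding_site,
    select_ligand,
)
from posedelta.synth import SyntheticSpec, make_host_guest

from conftest import make_atom


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestKabsch:
    def test_identity_on_self(self, rng):
        frame = rng.normal(size=(6, 3))
        moved, rot, trans = kabsch_superpose(frame, frame, np.arange(6))
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(moved, frame, atol=1e-9)

    def test_recovers_rigid_motion(self, rng):
        frame = rng.normal(size=(8, 3))
        target = frame @ random_rotation(rng).T + np.array([3.0, -1.0, 2.0])
        moved, rot, _ = kabsch_superpose(frame, target, np.arange(8))
        assert np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))) < 1e-9
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_planar_cross_optimal_rmsd_one(self):
        """Points (+-1,0,0),(0,+-1,0) vs their doubles: best fit is the
        identity and every deviation is 1, so the optimal RMSD is 1.0."""
        small = np.array([[1.0, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]])
        big = 2.0 * small
        moved, _, _ = kabsch_superpose(small, big, np.arange(4))
        rmsd = np.sqrt(np.mean(np.sum((moved - big) ** 2, axis=1)))
        assert rmsd == pytest.approx(1.0, abs=1e-9)

    def test_too_few_atoms(self, rng):
        frame = rng.normal(size=(5, 3))
        with pytest.raises(GeometryError):
            kabsch_superpose(frame, frame, np.array([0, 1]))

    def test_collinear_selection(self):
        frame = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError, match="collinear"):
            kabsch_superpose(frame, frame, np.arange(4))


def jittered_ensemble(seed=0, n_frames=20, sigma=0.1):
    hg = make_host_guest(SyntheticSpec(seed=seed, n_frames=n_frames, jitter_sigma=sigma))
    return hg.ensembles["A"]


class TestRmsd:
    def test_static_ensemble_all_zero(self):
        ens = jittered_ensemble(sigma=0.0, n_frames=5)
        backbone = select_backbone(ens.system)
        series = rmsd_series(ens, backbone)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_jittered_mean_in_expected_band(self):
        """Gaussian jitter sigma=0.1 A puts the mean backbone RMSD in a
        band around sigma*sqrt(3) (simulation oracle band 0.05-0.3 A)."""
        ens = jittered_ensemble(sigma=0.1)
        series = rmsd_series(ens, select_backbone(ens.system))
        assert 0.05 <= series.values[1:].mean() <= 0.3

    def test_fit_backbone_measure_ligand(self):
        ens = jittered_ensemble(sigma=0.1)
        series = rmsd_series(ens, select_backbone(ens.system), select_ligand(ens.system))
        assert np.all(series.values >= 0)
        assert series.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_mutual_symmetry(self, rng):
        """RMSD(a->b) equals RMSD(b->a) after optimal superposition."""
        a = rng.normal(size=(10, 3))
        b = a + rng.normal(0, 0.3, size=(10, 3))
        sel = np.arange(10)
        moved_ab, _, _ = kabsch_superpose(a, b, sel)
        moved_ba, _, _ = kabsch_superpose(b, a, sel)
        r_ab = np.sqrt(np.mean(np.sum((moved_ab - b) ** 2, axis=1)))
        r_ba = np.sqrt(np.mean(np.sum((moved_ba - a) ** 2, axis=1)))
        assert r_ab == pytest.approx(r_ba, abs=1e-9)

    def test_empty_selection_error(self):
        ens = jittered_ensemble(n_frames=3)
        with pytest.raises(TopologyError):
            rmsd_series(ens, np.array([], dtype=int))


class TestRmsf:
    def test_static_all_zero(self):
        ens = jittered_ensemble(sigma=0.0, n_frames=4)
        rmsf = rmsf_per_residue(ens, select_backbone(ens.system))
        np.testing.assert_allclose(rmsf.values, 0.0, atol=1e-9)

    def test_localised_jitter(self, rng):
        """Jittering only residue 7 leaves every other residue at zero."""
        ens = jittered_ensemble(sigma=0.0, n_frames=10)
        frames = ens.frames.copy()
        target = np.where(ens.system.residue_ids == 7)[0]
        fit_sel = np.where(ens.system.residue_ids <= 5)[0]
        frames[:, target, :] += rng.normal(0, 0.3, size=(10, target.size, 3))
        ens2 = SnapshotEnsemble(system=ens.system, frames=frames)
        rmsf = rmsf_per_residue(ens2, fit_sel)
        res = dict(zip(rmsf.residue_ids.tolist(), rmsf.values))
        assert res[7] > 0.1
        for rid, v in res.items():
            if rid != 7:
                assert v == pytest.approx(0.0, abs=1e-9)

    def test_global_rigid_motion_invariance(self, rng):
        ens = jittered_ensemble(sigma=0.1, n_frames=8)
        rot = random_rotation(rng)
        moved = SnapshotEnsemble(
            system=ens.system, frames=ens.frames @ rot.T + np.array([5.0, 1.0, -2.0])
        )
        sel = select_backbone(ens.system)
        a = rmsf_per_residue(ens, sel).values
        b = rmsf_per_residue(moved, sel).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_region_report_bookkeeping(self):
        ens = jittered_ensemble(sigma=0.1, n_frames=5)
        rmsf = rmsf_per_residue(ens, select_backbone(ens.system))
        regions = [RegionDefinition("H11", 1, 5), RegionDefinition("H12", 13, 15)]
        summary = region_summary(rmsf, regions)
        assert summary["H11"]["n_residues"] == 5
        assert summary["H12"]["n_residues"] == 3
        assert summary["H11"]["mean_rmsf"] > 0


class TestEnsembleSasa:
    def test_single_sphere(self):
        system = MolecularSystem(
            [make_atom(1, [0, 0, 0], gb_radius=1.6)], ligand_mask={1}, receptor_mask=set()
        )
        ens = SnapshotEnsemble(system=system, frames=np.zeros((1, 1, 3)))
        series = ensemble_sasa(ens)
        assert series.values[0] == pytest.approx(4 * np.pi * 3.0**2, rel=1e-6)

    def test_compact_smaller_than_stretched(self):
        def dimer(d):
            atoms = [
                make_atom(1, [0, 0, 0], gb_radius=1.6),
                make_atom(2, [d, 0, 0], gb_radius=1.6, residue_name="LIG", residue_id=2),
            ]
            system = MolecularSystem(atoms, ligand_mask={2})
            return SnapshotEnsemble(system=system, frames=system.reference_positions[None])

        compact = ensemble_sasa(dimer(2.0)).values[0]
        stretched = ensemble_sasa(dimer(5.0)).values[0]
        assert compact < stretched

    def test_sd_zero_for_identical_frames(self):
        ens = jittered_ensemble(sigma=0.0, n_frames=3)
        series = ensemble_sasa(ens)
        assert np.std(series.values) == 0.0

    def test_point_count_stability(self):
        """SASA changes by <= 0.5% between 960 and 5000 sphere points."""
        ens = jittered_ensemble(sigma=0.0, n_frames=1)
        coarse = ensemble_sasa(ens, points=960).values[0]
        fine = ensemble_sasa(ens, points=5000).values[0]
        assert abs(coarse - fine) / fine <= 0.005


class TestSelections:
    def test_binding_site_contains_pocket(self):
        ens = jittered_ensemble(sigma=0.0, n_frames=1)
        site = select_binding_site(ens.system, ens.frames[0], radius=5.0)
        assert site.size > 0
        assert set(np.unique(ens.system.residue_ids[site])).issubset(
            set(ens.system.residue_ids[ens.system.receptor_indices])
        )

    def test_backbone_names_only(self):
        ens = jittered_ensemble(sigma=0.0, n_frames=1)
        backbone = select_backbone(ens.system)
        names = {ens.system.atoms[i].name for i in backbone}
        assert names.issubset({"N", "CA", "C", "O"})
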