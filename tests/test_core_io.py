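"""Structure/parameter file round trips and their error contracts."""

import json

import numpy as np
import pytest

from posedelta import (
    ParseError,
    TopologyError,
    read_lj_sidecar,
    read_pdb_ensemble,
    read_pqr_parameters,
    read_sdf,
    write_pdb_ensemble,
)
from posedelta.core import MolecularSystem, net_charge
from posedelta.io import write_lj_sidecar, write_pqr
from posedelta.mm import frame_interaction
from posedelta.synth import SyntheticSpec, make_host_guest

from conftest import make_atom


def _toy_pdb(tmp_path, n_models=3, drop_atom_in_model=None):
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:4d}")
        atoms = [
            (1, "C1", "REC", 1, (0.0, 0.0, 0.0)),
            (2, "C2", "REC", 1, (2.0, 0.0, 0.0)),
            (3, "G1", "LIG", 9, (0.0, 3.0, 0.0)),
        ]
        if drop_atom_in_model == m:
            atoms = atoms[:-1]
        for serial, name, res, rid, (x, y, z) in atoms:
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{res:>4s} A{rid:4d}    "
                f"{x + 0.1 * m:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
        lines.append("ENDMDL")
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


class TestPdbEnsemble:
    def test_multi_model_round_trip(self, tmp_path):
        ens = read_pdb_ensemble(_toy_pdb(tmp_path))
        assert ens.n_frames == 3
        assert ens.system.n_atoms == 3
        assert ens.system.ligand_mask == {3}
        out = tmp_path / "rt.pdb"
        write_pdb_ensemble(ens, out)
        ens2 = read_pdb_ensemble(out)
        np.testing.assert_allclose(ens2.frames, ens.frames, atol=5e-4)

    def test_single_model_file(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "ATOM      1 C1   REC A   1       0.000   0.000   0.000  1.00  0.00\n"
            "ATOM      2 G1   LIG A   9       3.000   0.000   0.000  1.00  0.00\n"
        )
        ens = read_pdb_ensemble(path)
        assert ens.n_frames == 1

    def test_atom_count_mismatch_names_model(self, tmp_path):
        with pytest.raises(ParseError, match="model 2"):
            read_pdb_ensemble(_toy_pdb(tmp_path, drop_atom_in_model=2))

    def test_unknown_ligand_resname(self, tmp_path):
        with pytest.raises(ParseError, match="XYZ"):
            read_pdb_ensemble(_toy_pdb(tmp_path), ligand_resname="XYZ")

    def test_energy_stable_after_quantisation(self, tmp_path):
        """Once coordinates carry PDB precision, further round trips leave
        interaction energies bit-stable (atom order is preserved)."""
        hg = make_host_guest(SyntheticSpec(seed=5, n_frames=2))
        ens = hg.ensembles["A"]
        p1, p2 = tmp_path / "g1.pdb", tmp_path / "g2.pdb"
        write_pdb_ensemble(ens, p1)
        ens1 = read_pdb_ensemble(p1)
        for a, b in zip(ens1.system.atoms, ens.system.atoms):
            a.charge, a.gb_radius = b.charge, b.gb_radius
            a.lj_rmin_half, a.lj_epsilon = b.lj_rmin_half, b.lj_epsilon
        ens1.system.invalidate_cache()
        write_pdb_ensemble(ens1, p2)
        ens2 = read_pdb_ensemble(p2)
        for a, b in zip(ens2.system.atoms, ens.system.atoms):
            a.charge, a.gb_radius = b.charge, b.gb_radius
            a.lj_rmin_half, a.lj_epsilon = b.lj_rmin_half, b.lj_epsilon
        ens2.system.invalidate_cache()
        e1 = frame_interaction(ens1.system, ens1.frames[0]).e_int
        e2 = frame_interaction(ens2.system, ens2.frames[0]).e_int
        assert abs(e1 - e2) < 1e-9


class TestPqrSidecar:
    def _system(self):
        atoms = [
            make_atom(1, [0, 0, 0], name="C1", residue_name="REC"),
            make_atom(2, [3, 0, 0], name="G1", residue_id=9, residue_name="LIG"),
        ]
        return MolecularSystem(atoms, ligand_mask={2})

    def test_charges_attach_and_sum(self, tmp_path):
        path = tmp_path / "toy.pqr"
        path.write_text(
            "ATOM      1 C1   REC     1       0.0000     0.0000     0.0000    1.0000  1.5000\n"
            "ATOM      2 G1   LIG     9       3.0000     0.0000     0.0000   -1.0000  1.6000\n"
        )
        system = read_pqr_parameters(path, self._system())
        assert net_charge(system) == pytest.approx(0.0)
        assert system.atoms[1].gb_radius == pytest.approx(1.6)

    def test_unmatched_atom_is_hard_error(self, tmp_path):
        path = tmp_path / "toy.pqr"
        path.write_text(
            "ATOM      1 C1   REC     1       0.0000     0.0000     0.0000    1.0000  1.5000\n"
        )
        with pytest.raises(TopologyError, match="serial 2"):
            read_pqr_parameters(path, self._system())

    def test_zero_radius_violates_invariant(self, tmp_path):
        path = tmp_path / "toy.pqr"
        path.write_text(
            "ATOM      1 C1   REC     1       0.0000     0.0000     0.0000    1.0000  0.0000\n"
            "ATOM      2 G1   LIG     9       3.0000     0.0000     0.0000   -1.0000  1.6000\n"
        )
        with pytest.raises(TopologyError, match="radius"):
            read_pqr_parameters(path, self._system())

    def test_sidecar_missing_serial_listed(self, tmp_path):
        system = self._system()
        path = tmp_path / "lj.json"
        path.write_text(json.dumps({"lj": {"1": {"rmin_half": 1.7, "epsilon": 0.1}}}))
        with pytest.raises(TopologyError, match=r"\[2\]"):
            read_lj_sidecar(path, system)

    def test_pqr_sidecar_round_trip(self, tmp_path):
        hg = make_host_guest(SyntheticSpec(seed=3, n_frames=1))
        system = hg.ensembles["A"].system
        write_pqr(system, tmp_path / "s.pqr")
        write_lj_sidecar(system, tmp_path / "s.json")
        fresh = make_host_guest(SyntheticSpec(seed=3, n_frames=1)).ensembles["A"].system
        for a in fresh.atoms:
            a.charge, a.gb_radius = 0.0, 1.0
            a.lj_rmin_half, a.lj_epsilon = 1.0, 0.0
        fresh.invalidate_cache()
        read_pqr_parameters(tmp_path / "s.pqr", fresh)
        read_lj_sidecar(tmp_path / "s.json", fresh)
        np.testing.assert_allclose(fresh.charges, system.charges, atol=5e-5)
        np.testing.assert_allclose(fresh.lj_epsilon, system.lj_epsilon)


MINI_SDF = """{title}
  posedelta

{counts}
{body}M  END
$$$$
"""


def _write_sdf(tmp_path, title, n_atoms, n_bonds, body):
    counts = f"{n_atoms:3d}{n_bonds:3d}  0  0  0  0  0  0  0  0999 V2000"
    path = tmp_path / f"{title}.sdf"
    path.write_text(MINI_SDF.format(title=title, counts=counts, body=body))
    return path


class TestSdf:
    def test_pomolic_acid_heavy_atom_count(self):
        """C30H48O4 has 34 heavy atoms and 48 hydrogens in total."""
        from posedelta.data import ligand_sdf_path

        graph = read_sdf(ligand_sdf_path("pomolic_acid"))
        assert graph.n_atoms == 34
        assert sum(1 for a in graph.atoms if a.atomic_number == 6) == 30
        assert sum(1 for a in graph.atoms if a.atomic_number == 8) == 4
        assert sum(a.n_hydrogens for a in graph.atoms) == 48

    def test_methane(self, tmp_path):
        body = "    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
        graph = read_sdf(_write_sdf(tmp_path, "methane", 1, 0, body))
        assert graph.n_atoms == 1
        assert graph.atoms[0].n_hydrogens == 4

    def test_cyclohexane_ring_flags(self, tmp_path):
        body = ""
        for k in range(6):
            body += f"    {float(k):.4f}    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
        for k in range(6):
            body += f"{k + 1:3d}{(k + 1) % 6 + 1:3d}  1  0\n"
        graph = read_sdf(_write_sdf(tmp_path, "cyclohexane", 6, 6, body))
        assert all(a.in_ring for a in graph.atoms)
        assert all(a.n_hydrogens == 2 for a in graph.atoms)

    def test_v3000_rejected(self, tmp_path):
        path = tmp_path / "v3.sdf"
        path.write_text("t\n\n\n  0  0  0  0  0  0  0  0  0  0999 V3000\nM  END\n$$$$\n")
        with pytest.raises(ParseError, match="V3000"):
            read_sdf(path)

    def test_malformed_counts_line(self, tmp_path):
        path = tmp_path / "bad.sdf"
        path.write_text("t\n\n\nnot a counts line\nM  END\n$$$$\n")
        with pytest.raises(ParseError):
            read_sdf(path)
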