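"""Readers and writers for the formats the pipeline touches.

Multi-MODEL PDB carries snapshot ensembles; PQR carries per-atom charge and
intrinsic Born radius; a JSON sidecar carries the Lennard-Jones parameters
(and optionally GB screening factors) that PQR has no columns for; SDF V2000
carries small-molecule graphs.

Sidecar schema (JSON object)::

    {
      "lj":        {"<serial>": {"rmin_half": <A>, "epsilon": <kcal/mol>}, ...},
      "gb_screen": {"<serial>": <dimensionless>, ...}   # optional
    }
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from rdkit import Chem

from .core import AtomRecord, GraphAtom, GraphBond, LigandGraph, MolecularSystem, SnapshotEnsemble
from .errors import ParseError, TopologyError

DEFAULT_LIGAND_RESNAME = "LIG"


# -- PDB ------------------------------------------------------------------

def _parse_pdb_atom_line(line: str):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        resid = int(line[22:26])
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except ValueError as exc:
        raise ParseError(f"malformed PDB atom line: {line.rstrip()!r}") from exc
    return serial, name, resname, chain, resid, xyz


def read_pdb_ensemble(path: str | Path, ligand_resname: str = DEFAULT_LIGAND_RESNAME) -> SnapshotEnsemble:
    """Read a (possibly multi-MODEL) PDB file into a snapshot ensemble.

    The ligand is identified by residue name; every model must contain the
    same atoms in the same order.
    """
    path = Path(path)
    models: list[list[tuple]] = []
    current: list[tuple] | None = None
    in_model = False
    with path.open() as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                current = []
            elif rec == "ENDMDL":
                if current is None:
                    raise ParseError("ENDMDL without MODEL")
                models.append(current)
                current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    if in_model:
                        raise ParseError("atom record outside MODEL block")
                    current = []
                current.append(_parse_pdb_atom_line(line))
                if not in_model:
                    pass
    if current:  # single-model file without MODEL records
        models.append(current)
    if not models or not models[0]:
        raise ParseError(f"{path}: no atom records found")

    first = models[0]
    n_atoms = len(first)
    for m_idx, model in enumerate(models[1:], start=2):
        if len(model) != n_atoms:
            raise ParseError(
                f"{path}: model {m_idx} has {len(model)} atoms, expected {n_atoms}"
            )
        for a, b in zip(first, model):
            if (a[0], a[1]) != (b[0], b[1]):
                raise ParseError(
                    f"{path}: model {m_idx}: atom order differs "
                    f"(serial {b[0]} name {b[1]!r} vs serial {a[0]} name {a[1]!r})"
                )

    atoms = [
        AtomRecord(serial=s, name=n, residue_id=rid, residue_name=rn, chain=ch,
                   position=np.asarray(xyz))
        for s, n, rn, ch, rid, xyz in first
    ]
    ligand_mask = {a.serial for a in atoms if a.residue_name == ligand_resname}
    if not ligand_mask:
        names = sorted({a.residue_name for a in atoms})
        raise ParseError(
            f"{path}: no residue named {ligand_resname!r}; present residues: {names}"
        )
    system = MolecularSystem(atoms, ligand_mask=ligand_mask)
    frames = np.asarray([[rec[5] for rec in model] for model in models], dtype=float)
    return SnapshotEnsemble(system=system, frames=frames)


def write_pdb_ensemble(ensemble: SnapshotEnsemble, path: str | Path) -> None:
    """Write every frame as a MODEL block with fixed-column ATOM records."""
    path = Path(path)
    sys_ = ensemble.system
    with path.open("w") as fh:
        for f_idx in range(ensemble.n_frames):
            fh.write(f"MODEL     {f_idx + 1:4d}\n")
            for a, xyz in zip(sys_.atoms, ensemble.frames[f_idx]):
                fh.write(
                    f"ATOM  {a.serial:5d} {a.name:<4.4s}{a.residue_name:>4.3s} "
                    f"{a.chain:1.1s}{a.residue_id:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# -- PQR + sidecar --------------------------------------------------------

def read_pqr_parameters(path: str | Path, system: MolecularSystem) -> MolecularSystem:
    """Attach charges and intrinsic Born radii from a PQR file.

    Atoms are matched by (serial, name); any PQR atom without a partner in
    ``system`` (or vice versa) is a hard error.
    """
    path = Path(path)
    seen: dict[tuple[int, str], tuple[float, float]] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            tok = line.split()
            # ATOM serial name resName [chain] resSeq x y z q r
            if len(tok) < 10:
                raise ParseError(f"malformed PQR line: {line.rstrip()!r}")
            try:
                serial = int(tok[1])
                charge, radius = float(tok[-2]), float(tok[-1])
            except ValueError as exc:
                raise ParseError(f"malformed PQR line: {line.rstrip()!r}") from exc
            seen[(serial, tok[2])] = (charge, radius)

    matched = set()
    for atom in system.atoms:
        key = (atom.serial, atom.name)
        if key not in seen:
            raise TopologyError(
                f"PQR has no entry for atom serial {atom.serial} name {atom.name!r}"
            )
        charge, radius = seen[key]
        if not radius > 0:
            raise TopologyError(
                f"atom {atom.serial} ({atom.name}): PQR radius must be > 0, got {radius}"
            )
        atom.charge = charge
        atom.gb_radius = radius
        matched.add(key)
    extra = sorted(set(seen) - matched)
    if extra:
        raise TopologyError(f"PQR atoms with no match in system: {extra}")
    system.invalidate_cache()
    return system


def read_lj_sidecar(path: str | Path, system: MolecularSystem) -> MolecularSystem:
    """Attach LJ parameters (and optional GB screens) from the JSON sidecar."""
    with Path(path).open() as fh:
        data = json.load(fh)
    lj = data.get("lj", {})
    missing = [a.serial for a in system.atoms if str(a.serial) not in lj]
    if missing:
        raise TopologyError(f"sidecar missing LJ entries for serials {missing}")
    for atom in system.atoms:
        entry = lj[str(atom.serial)]
        atom.lj_rmin_half = float(entry["rmin_half"])
        atom.lj_epsilon = float(entry["epsilon"])
        if atom.lj_epsilon < 0:
            raise TopologyError(f"atom {atom.serial}: negative LJ epsilon in sidecar")
    for serial, screen in data.get("gb_screen", {}).items():
        atom = system.atoms[system.index_of(int(serial))]
        atom.gb_screen = float(screen)
    system.invalidate_cache()
    return system


def write_pqr(system: MolecularSystem, path: str | Path, frame: np.ndarray | None = None) -> None:
    coords = system.reference_positions if frame is None else np.asarray(frame)
    with Path(path).open("w") as fh:
        for a, xyz in zip(system.atoms, coords):
            fh.write(
                f"ATOM  {a.serial:5d} {a.name:<4.4s} {a.residue_name:<4.4s} "
                f"{a.residue_id:4d}    "
                f"{xyz[0]:10.4f} {xyz[1]:10.4f} {xyz[2]:10.4f} "
                f"{a.charge:9.4f} {a.gb_radius:7.4f}\n"
            )
        fh.write("END\n")


def write_lj_sidecar(system: MolecularSystem, path: str | Path) -> None:
    data = {
        "lj": {
            str(a.serial): {"rmin_half": a.lj_rmin_half, "epsilon": a.lj_epsilon}
            for a in system.atoms
        },
        "gb_screen": {str(a.serial): a.gb_screen for a in system.atoms},
    }
    with Path(path).open("w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


# -- SDF ------------------------------------------------------------------

_BOND_ORDER = {Chem.BondType.SINGLE: 1.0, Chem.BondType.DOUBLE: 2.0,
               Chem.BondType.TRIPLE: 3.0, Chem.BondType.AROMATIC: 1.5}


def read_sdf(path: str | Path) -> LigandGraph:
    """Read the first molecule of an SDF (V2000) file as a heavy-atom graph.

    Hydrogens are folded into per-atom attached-H counts; aromaticity is
    perceived on the kekulised input and recorded as bond order 1.5.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if len(lines) < 4:
        raise ParseError(f"{path}: truncated SDF")
    counts = lines[3]
    if "V3000" in counts:
        raise ParseError(f"{path}: V3000 connection tables are not supported")
    if "V2000" not in counts:
        raise ParseError(f"{path}: malformed counts line: {counts!r}")
    mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
    if mol is None:
        raise ParseError(f"{path}: RDKit could not parse the connection table")
    return ligand_graph_from_mol(mol)


def ligand_graph_from_mol(mol: "Chem.Mol") -> LigandGraph:
    """Convert an RDKit molecule (H-suppressed) to a :class:`LigandGraph`."""
    atoms = [
        GraphAtom(
            atomic_number=a.GetAtomicNum(),
            formal_charge=a.GetFormalCharge(),
            n_hydrogens=a.GetTotalNumHs(),
            in_ring=a.IsInRing(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        order = _BOND_ORDER.get(b.GetBondType())
        if order is None:
            raise ParseError(f"unsupported bond type {b.GetBondType()}")
        bonds.append(GraphBond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return LigandGraph(atoms, bonds)
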