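"""Molecule and receptor data model plus readers/writers.

The canonical in-memory unit is the heavy-atom molecular graph: hydrogens are
dropped on ingestion (their count is retained per atom so molecules round-trip
through SMILES), because pose accuracy is evaluated against heavy-atom crystal
positions. Coordinates are Angstrom, right-handed, exactly as stored in the
source PDB/SDF — no recentering happens at read time; all transforms belong to
the superposition module.

RDKit does the chemical perception (SMILES grammar, aromaticity, file
formats); gemmi reads and writes receptor PDB files. The types here are plain
dataclasses so downstream numerical code never touches a toolkit object.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .errors import DataError, FormatError, ValidationError

# RDKit writes parse diagnostics to the console; errors are re-raised as
# FormatError with record context instead.
RDLogger.DisableLog("rdApp.*")

AROMATIC = "aromatic"

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    AROMATIC: Chem.BondType.AROMATIC,
}
_BOND_ORDERS = {v: k for k, v in _BOND_TYPES.items()}


@dataclass
class Atom:
    """One heavy atom: element symbol, charge, attached-H count, coordinates."""

    element: str
    formal_charge: int = 0
    n_hydrogens: int = 0
    aromatic: bool = False
    coords: np.ndarray | None = None


@dataclass
class Bond:
    """Heavy-atom bond between atom indices ``i`` and ``j``."""

    i: int
    j: int
    order: int | str = 1


@dataclass
class Molecule:
    """Element-labeled heavy-atom graph with optional 3D coordinates."""

    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    name: str | None = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValidationError(
                    f"molecule {self.id!r}: bond ({b.i},{b.j}) references missing atom"
                )
            if b.i == b.j:
                raise ValidationError(f"molecule {self.id!r}: self-bond on atom {b.i}")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValidationError(f"molecule {self.id!r}: duplicate bond {key}")
            seen.add(key)
        with_coords = [a for a in self.atoms if a.coords is not None]
        if with_coords and len(with_coords) != n:
            raise ValidationError(
                f"molecule {self.id!r}: coordinates present on only "
                f"{len(with_coords)}/{n} heavy atoms"
            )

    @property
    def heavy_atom_count(self) -> int:
        return len(self.atoms)

    @property
    def has_coords(self) -> bool:
        return bool(self.atoms) and self.atoms[0].coords is not None

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of heavy-atom coordinates in Angstrom."""
        if not self.has_coords:
            raise DataError(f"molecule {self.id!r} has no coordinates")
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "Molecule":
        """Copy of this molecule with coordinates replaced by ``xyz``."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise DataError(
                f"coordinate array shape {xyz.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, coords=xyz[k].copy()) for k, a in enumerate(self.atoms)]
        return Molecule(self.id, atoms, [replace(b) for b in self.bonds], self.name)

    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# RDKit conversion


def to_rdkit(mol: Molecule, with_coords: bool = False) -> Chem.Mol:
    """Rebuild an RDKit molecule from the heavy-atom graph.

    Hydrogen counts recorded at ingestion are restored as explicit-H counts so
    aromatic perception (e.g. pyrrole NH) survives the round trip.
    """
    rw = Chem.RWMol()
    for a in mol.atoms:
        try:
            ra = Chem.Atom(a.element)
        except RuntimeError as exc:  # unknown element symbol
            raise FormatError(f"molecule {mol.id!r}: unknown element {a.element!r}") from exc
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNumExplicitHs(a.n_hydrogens)
        ra.SetNoImplicit(True)
        ra.SetIsAromatic(a.aromatic)
        rw.AddAtom(ra)
    for b in mol.bonds:
        rw.AddBond(b.i, b.j, _BOND_TYPES[b.order])
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:
        raise FormatError(f"molecule {mol.id!r} fails chemical sanitization: {exc}") from exc
    if with_coords:
        conf = Chem.Conformer(out.GetNumAtoms())
        for k, a in enumerate(mol.atoms):
            if a.coords is None:
                raise DataError(f"molecule {mol.id!r} has no coordinates")
            conf.SetAtomPosition(k, tuple(float(x) for x in a.coords))
        out.AddConformer(conf)
    return out


def from_rdkit(rdmol: Chem.Mol, mol_id: str, name: str | None = None,
               keep_coords: bool = False) -> Molecule:
    """Convert an RDKit molecule to the heavy-atom :class:`Molecule`."""
    rd = Chem.RemoveHs(rdmol)
    heavy_idx = [a.GetIdx() for a in rd.GetAtoms() if a.GetAtomicNum() != 1]
    index_map = {old: new for new, old in enumerate(heavy_idx)}
    conf = rd.GetConformer() if (keep_coords and rd.GetNumConformers()) else None
    atoms = []
    for old in heavy_idx:
        a = rd.GetAtomWithIdx(old)
        coords = None
        if conf is not None:
            p = conf.GetAtomPosition(old)
            coords = np.array([p.x, p.y, p.z], dtype=float)
        atoms.append(Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs(),
                          a.GetIsAromatic(), coords))
    bonds = []
    for b in rd.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i not in index_map or j not in index_map:
            continue
        order = _BOND_ORDERS.get(b.GetBondType())
        if order is None:
            raise FormatError(
                f"molecule {mol_id!r}: unsupported bond type {b.GetBondType()}"
            )
        bonds.append(Bond(index_map[i], index_map[j], order))
    return Molecule(mol_id, atoms, bonds, name)


# ---------------------------------------------------------------------------
# Small-molecule readers/writers


def parse_smiles(text: str, mol_id: str = "", name: str | None = None) -> Molecule:
    """Parse a SMILES string into a heavy-atom :class:`Molecule` (no coords)."""
    if not text or not text.strip():
        raise FormatError(f"record {mol_id!r}: empty SMILES string")
    rdmol = Chem.MolFromSmiles(text)
    if rdmol is None:
        raise FormatError(f"record {mol_id!r}: unparseable SMILES {text!r}")
    return from_rdkit(rdmol, mol_id or text, name)


def canonical_smiles(mol: Molecule) -> str:
    return Chem.MolToSmiles(to_rdkit(mol))


def read_pose_file(path: str | Path, mol_id: str | None = None) -> Molecule:
    """Read a ligand pose (SDF/MOL or PDB) preserving atom order and coords."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"pose file {path} does not exist")
    suffix = path.suffix.lower()
    if suffix in {".sdf", ".mol"}:
        rdmol = Chem.MolFromMolFile(str(path), removeHs=False)
    elif suffix == ".pdb":
        rdmol = Chem.MolFromPDBFile(str(path), removeHs=False)
    else:
        raise FormatError(f"pose file {path}: unsupported format {suffix!r}")
    if rdmol is None:
        raise FormatError(f"pose file {path}: unparseable {suffix} content")
    if rdmol.GetNumConformers() == 0:
        raise DataError(f"pose file {path}: no coordinates")
    mol = from_rdkit(rdmol, mol_id or path.stem, keep_coords=True)
    if not mol.has_coords:
        raise DataError(f"pose file {path}: no heavy-atom coordinates")
    if not np.all(np.isfinite(mol.coords)):
        raise DataError(f"pose file {path}: non-finite coordinates")
    return mol


def write_pose_sdf(mol: Molecule, path: str | Path) -> None:
    """Write a molecule with coordinates as an SDF (MOL V2000) file."""
    rdmol = to_rdkit(mol, with_coords=True)
    writer = Chem.SDWriter(str(path))
    try:
        rdmol.SetProp("_Name", mol.name or mol.id)
        writer.write(rdmol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# SMILES library files (one record per line: SMILES<TAB>ID)


def read_smiles_library(path: str | Path) -> list[Molecule]:
    mols = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected 'SMILES<TAB>ID', got {line!r}"
            )
        smiles, frag_id = parts[0].strip(), parts[1].strip()
        mols.append(parse_smiles(smiles, frag_id))
    if not mols:
        raise FormatError(f"{path}: empty library file")
    return mols


def write_smiles_library(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (smiles, id) records as a tab-separated library file."""
    with open(path, "w") as fh:
        for smiles, frag_id in records:
            fh.write(f"{smiles}\t{frag_id}\n")


# ---------------------------------------------------------------------------
# Stage 1 submissions and Stage 3 follow-ups

_BOOL_DIALECT = {"True": True, "true": True, "1": True,
                 "False": False, "false": False, "0": False}


@dataclass(frozen=True)
class SubmissionRecordS1:
    """One screening prediction: fragment identifier and binder verdict."""

    fragment_id: str
    predicted_binder: bool


def read_stage1_submission(path: str | Path) -> list[SubmissionRecordS1]:
    """Read a screening submission CSV (header row, strict boolean dialect)."""
    records: list[SubmissionRecordS1] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty submission file") from None
        if len(header) < 2:
            raise FormatError(f"{path}: need fragment-ID and prediction columns")
        for rowno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise ValidationError(f"{path}:{rowno}: missing prediction column")
            frag_id = row[0].strip()
            if not frag_id:
                raise ValidationError(f"{path}:{rowno}: empty fragment id")
            if frag_id in seen:
                raise ValidationError(f"{path}:{rowno}: duplicate fragment id {frag_id!r}")
            raw = row[1].strip()
            if raw not in _BOOL_DIALECT:
                raise ValidationError(
                    f"{path}:{rowno}: unparseable boolean {raw!r} "
                    f"(allowed: True/False/true/false/1/0)"
                )
            seen.add(frag_id)
            records.append(SubmissionRecordS1(frag_id, _BOOL_DIALECT[raw]))
    if not records:
        raise FormatError(f"{path}: no prediction rows")
    return records


def write_stage1_submission(records: Sequence[SubmissionRecordS1],
                            path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fragment_id", "predicted_binder"])
        for r in records:
            writer.writerow([r.fragment_id, "True" if r.predicted_binder else "False"])


@dataclass(frozen=True)
class FollowUpRecord:
    """Stage 3 follow-up suggestion: SMILES, supplier id, confidence in [0,10]."""

    smiles: str
    supplier_id: str
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 10.0):
            raise ValidationError(
                f"follow-up {self.supplier_id!r}: confidence {self.confidence} "
                f"outside [0, 10]"
            )


def read_followups(path: str | Path, validate_range: bool = True) -> list[FollowUpRecord]:
    """Read a Stage 3 follow-up CSV (smiles, supplier_id, confidence)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty follow-up file") from None
        for rowno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 3:
                raise ValidationError(f"{path}:{rowno}: need smiles, supplier_id, confidence")
            try:
                conf = float(row[2])
            except ValueError:
                raise ValidationError(
                    f"{path}:{rowno}: unparseable confidence {row[2]!r}"
                ) from None
            if not validate_range:
                conf = min(10.0, max(0.0, conf))
            records.append(FollowUpRecord(row[0].strip(), row[1].strip(), conf))
    if not records:
        raise FormatError(f"{path}: no follow-up rows")
    return records


# ---------------------------------------------------------------------------
# Receptor model and PDB I/O


@dataclass
class Residue:
    name: str
    seqnum: int
    atoms: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Receptor:
    """Protein chains with residue atoms; C-alpha extraction for alignment."""

    chains: list[tuple[str, list[Residue]]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for chain_id, residues in self.chains:
            for res in residues:
                key = (chain_id, res.seqnum)
                if key in seen:
                    raise ValidationError(f"duplicate residue {key} in receptor")
                seen.add(key)

    def ca_atoms(self) -> list[tuple[tuple[str, int], np.ndarray]]:
        """[(chain, resnum), xyz] pairs for atoms named CA, ordered by chain+number."""
        out = []
        for chain_id, residues in sorted(self.chains, key=lambda c: c[0]):
            for res in sorted(residues, key=lambda r: r.seqnum):
                if "CA" in res.atoms:
                    xyz = res.atoms["CA"]
                    if not np.all(np.isfinite(xyz)):
                        raise DataError(
                            f"non-finite CA coordinates at {(chain_id, res.seqnum)}"
                        )
                    out.append(((chain_id, res.seqnum), xyz))
        return out


def read_receptor_pdb(path: str | Path) -> Receptor:
    """Read a receptor PDB (ATOM/HETATM subset; highest-occupancy altloc)."""
    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    if len(st) == 0:
        raise FormatError(f"{path}: no models in PDB file")
    chains = []
    for chain in st[0]:
        residues = []
        for res in chain:
            atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
            residues.append(Residue(res.name, res.seqid.num, atoms))
        chains.append((chain.name, residues))
    return Receptor(chains)


def write_receptor_pdb(receptor: Receptor, path: str | Path) -> None:
    st = gemmi.Structure()
    st.name = "fragchal"
    model = gemmi.Model("1")
    for chain_id, residues in receptor.chains:
        chain = gemmi.Chain(chain_id)
        for res in residues:
            r = gemmi.Residue()
            r.name = res.name
            r.seqid = gemmi.SeqId(res.seqnum, " ")
            for atom_name, xyz in res.atoms.items():
                a = gemmi.Atom()
                a.name = atom_name
                a.element = gemmi.Element(atom_name[:1])
                a.pos = gemmi.Position(*[float(x) for x in xyz])
                r.add_atom(a)
            chain.add_residue(r)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
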