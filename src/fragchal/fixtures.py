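"""Synthetic-data generators: every challenge stage is testable offline.

Real challenge data (the 799-fragment library, deposited crystal structures,
participant submissions) live in external archives. The generators here
stand in for them with objects whose ground truth is known by construction:

* a toy fragment library drawn from a template grammar (ring cores plus a
  substituent menu), deterministic given a seed;
* perturbed ligand poses whose exact index-matched RMSD to the reference is
  computed directly from the applied rigid motion and noise;
* simulated Boolean screening submissions with chosen sensitivity and
  specificity;
* a minimal synthetic receptor — an ideal alpha-helix of C-alpha
  pseudo-atoms — sufficient for superposition tests.

Small-molecule fixture coordinates are tabulated idealized geometries, not
embedder output, so RMSD oracles are decoupled from any conformer code. All
generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem import (Atom, Bond, Molecule, Receptor, Residue, SubmissionRecordS1,
                   parse_smiles, write_smiles_library)
from .errors import ValidationError
from .screening import GroundTruth, Label
from .symrmsd import naive_rmsd

# ---------------------------------------------------------------------------
# Tabulated idealized geometries (Angstrom)


def _ring_coords(n: int, radius: float) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(n)])


def fixture_molecule(name: str) -> Molecule:
    """Named small-molecule fixture with idealized 3D coordinates."""
    if name == "benzene":
        xyz = _ring_coords(6, 1.39)
        atoms = [Atom("C", aromatic=True, n_hydrogens=1, coords=xyz[k])
                 for k in range(6)]
        bonds = [Bond(k, (k + 1) % 6, "aromatic") for k in range(6)]
        return Molecule("benzene", atoms, bonds)
    if name == "dimethyl_ether":  # C-O-C, mirror-symmetric
        xyz = np.array([[-1.17, 0.26, 0.0], [0.0, -0.52, 0.0], [1.17, 0.26, 0.0]])
        atoms = [Atom("C", n_hydrogens=3, coords=xyz[0]),
                 Atom("O", coords=xyz[1]),
                 Atom("C", n_hydrogens=3, coords=xyz[2])]
        return Molecule("dimethyl_ether", atoms, [Bond(0, 1), Bond(1, 2)])
    if name == "para_xylene":  # para-disubstituted ring: 2-fold symmetry
        ring = _ring_coords(6, 1.39)
        methyls = np.array([ring[0] * (1.39 + 1.50) / 1.39,
                            ring[3] * (1.39 + 1.50) / 1.39])
        atoms = ([Atom("C", aromatic=True, n_hydrogens=1 if k not in (0, 3) else 0,
                       coords=ring[k]) for k in range(6)]
                 + [Atom("C", n_hydrogens=3, coords=methyls[0]),
                    Atom("C", n_hydrogens=3, coords=methyls[1])])
        bonds = ([Bond(k, (k + 1) % 6, "aromatic") for k in range(6)]
                 + [Bond(0, 6), Bond(3, 7)])
        return Molecule("para_xylene", atoms, bonds)
    if name == "ethanol":
        xyz = np.array([[-0.89, 0.17, 0.0], [0.56, -0.31, 0.0], [1.44, 0.79, 0.0]])
        atoms = [Atom("C", n_hydrogens=3, coords=xyz[0]),
                 Atom("C", n_hydrogens=2, coords=xyz[1]),
                 Atom("O", n_hydrogens=1, coords=xyz[2])]
        return Molecule("ethanol", atoms, [Bond(0, 1), Bond(1, 2)])
    raise ValidationError(f"unknown fixture molecule {name!r}")


def molecule_with_random_coords(smiles: str, mol_id: str, seed: int,
                                scale: float = 3.0) -> Molecule:
    """Parse SMILES and attach seeded random coordinates.

    The geometry is not chemically meaningful — it does not have to be: RMSD
    and isomorphism machinery only sees a labeled graph plus points.
    """
    mol = parse_smiles(smiles, mol_id)
    rng = np.random.default_rng(seed)
    return mol.with_coords(rng.normal(scale=scale, size=(mol.heavy_atom_count, 3)))


# ---------------------------------------------------------------------------
# Toy SMILES library

_CORES = [
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "C1CCNCC1", "C1CCOCC1", "C1CCCCC1", "c1cnccn1", "c1ccc2ccccc2c1",
]
_TEMPLATES_1 = [
    "c1ccc({s})cc1", "c1ccc({s})nc1", "c1cc({s})co1", "c1cc({s})cs1",
    "C1CCC({s})CC1", "C1CCN({s})CC1", "c1cc({s})cnc1",
]
_TEMPLATES_2 = [
    "c1cc({s1})cc({s2})c1", "c1cc({s1})c({s2})cc1", "c1nc({s1})cc({s2})c1",
]
_SUBSTITUENTS = ["C", "CC", "O", "N", "F", "Cl", "Br", "OC", "C#N",
                 "C(=O)O", "C(=O)N", "C(F)(F)F", "S(C)(=O)=O", "CO", "CN"]


def make_toy_library(n: int, seed: int = 0,
                     path: str | Path | None = None) -> list[tuple[str, str]]:
    """``n`` fragment-like (smiles, id) records; ids F1..Fn; 3-25 heavy atoms.

    Drawn deterministically from a template grammar of ring cores and a
    substituent menu, emulating the size and chemotype range of a screening
    library without reproducing any real one.
    """
    if n < 1:
        raise ValidationError("library size must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    k = 0
    while len(records) < n:
        k += 1
        choice = rng.integers(0, 3)
        if choice == 0:
            smiles = _CORES[rng.integers(0, len(_CORES))]
        elif choice == 1:
            tpl = _TEMPLATES_1[rng.integers(0, len(_TEMPLATES_1))]
            smiles = tpl.format(s=_SUBSTITUENTS[rng.integers(0, len(_SUBSTITUENTS))])
        else:
            tpl = _TEMPLATES_2[rng.integers(0, len(_TEMPLATES_2))]
            smiles = tpl.format(s1=_SUBSTITUENTS[rng.integers(0, len(_SUBSTITUENTS))],
                                s2=_SUBSTITUENTS[rng.integers(0, len(_SUBSTITUENTS))])
        try:
            mol = parse_smiles(smiles, f"F{len(records) + 1}")
        except Exception:
            continue
        if not (3 <= mol.heavy_atom_count <= 25):
            continue
        records.append((smiles, f"F{len(records) + 1}"))
    if path is not None:
        write_smiles_library(records, path)
    return records


# ---------------------------------------------------------------------------
# Perturbed poses of known RMSD


@dataclass(frozen=True)
class PerturbSpec:
    """Rigid rotation (degrees, about the centroid), translation magnitude
    (Angstrom), per-atom isotropic Gaussian noise SD (Angstrom), and seed."""

    rotation_deg: float = 0.0
    translation: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_deg < 0 or self.translation < 0 or self.noise_sd < 0:
            raise ValidationError("perturbation magnitudes must be >= 0")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _axis_angle_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def make_perturbed_pose(reference: Molecule, spec: PerturbSpec
                        ) -> tuple[Molecule, float]:
    """Seeded rigid rotation + translation + noise; returns (pose, exact
    index-matched RMSD to the reference)."""
    X = reference.coords
    rng = np.random.default_rng(spec.seed)
    centroid = X.mean(axis=0)
    R = _axis_angle_matrix(_random_unit(rng), np.deg2rad(spec.rotation_deg))
    Y = (X - centroid) @ R.T + centroid
    Y = Y + _random_unit(rng) * spec.translation
    if spec.noise_sd > 0:
        Y = Y + rng.normal(scale=spec.noise_sd, size=Y.shape)
    pose = reference.with_coords(Y)
    pose.id = f"{reference.id}_perturbed"
    return pose, naive_rmsd(pose, reference)


def shuffle_atom_order(mol: Molecule, seed: int = 0) -> tuple[Molecule, np.ndarray]:
    """Relabel atoms by a seeded random permutation; returns (molecule, perm)
    with new_index = perm[old_index]."""
    rng = np.random.default_rng(seed)
    n = mol.heavy_atom_count
    perm = rng.permutation(n)
    atoms = [None] * n
    for old, a in enumerate(mol.atoms):
        atoms[perm[old]] = Atom(a.element, a.formal_charge, a.n_hydrogens,
                                a.aromatic,
                                None if a.coords is None else a.coords.copy())
    bonds = [Bond(int(perm[b.i]), int(perm[b.j]), b.order) for b in mol.bonds]
    return Molecule(mol.id, atoms, bonds, mol.name), perm


# ---------------------------------------------------------------------------
# Simulated screening submissions


def make_submission_with_accuracy(gt: GroundTruth, sensitivity: float,
                                  specificity: float, seed: int = 0
                                  ) -> list[SubmissionRecordS1]:
    """Boolean submission that is correct on each positive with probability
    ``sensitivity`` and on each negative with probability ``specificity``."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValidationError("sensitivity and specificity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for fid in gt.non_excluded_ids:
        if gt.labels[fid] is Label.POSITIVE:
            pred = bool(rng.random() < sensitivity)
        else:
            pred = not bool(rng.random() < specificity)
        records.append(SubmissionRecordS1(fid, pred))
    return records


# ---------------------------------------------------------------------------
# Synthetic receptor


def make_synthetic_receptor(n_residues: int = 30, chain_id: str = "A",
                            offset: int = 1) -> Receptor:
    """Ideal alpha-helix of C-alpha pseudo-atoms (rise 1.5 A, 100 deg/residue,
    radius 2.3 A) — a minimal receptor for alignment tests."""
    if n_residues < 3:
        raise ValidationError("need at least 3 residues")
    residues = []
    for k in range(n_residues):
        theta = np.deg2rad(100.0 * k)
        xyz = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * k])
        residues.append(Residue("ALA", offset + k, {"CA": xyz}))
    return Receptor([(chain_id, residues)])
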