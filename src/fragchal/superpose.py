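"""Optimal rigid-body superposition (Kabsch) and transform propagation.

The pose-evaluation pipeline aligns the C-alpha trace of a predicted
receptor onto the experimental receptor and carries the ligand along with the
fitted transform, so ligand RMSD is measured in the crystallographic frame.

The Kabsch solution minimizes sum_k ||R x_k + t - y_k||^2 over proper
rotations R and translations t: center both point sets, take the SVD of the
covariance H = P^T Q, and form R = V diag(1, 1, det(V U^T)) U^T. The
determinant correction flips the smallest singular direction when the
unconstrained optimum is a reflection, so ligand chirality is never silently
mirrored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chem import Molecule, Receptor
from .errors import (DataError, DegenerateGeometryWarning,
                     InsufficientPointsError, PairingError)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation (det +1) plus translation, both in Angstrom space."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise DataError("rigid transform needs a 3x3 rotation and 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise DataError("rotation must be orthonormal with determinant +1")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.rotation.T + self.translation

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``first`` then ``self``."""
        return RigidTransform(self.rotation @ first.rotation,
                              self.rotation @ first.translation + self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray
               ) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Points are index-paired. Returns the transform and the minimized RMSD.
    Near-collinear point sets trigger :class:`DegenerateGeometryWarning`; the
    fit is still returned.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DataError(f"point sets must both be (N, 3); got {P.shape} and {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise InsufficientPointsError(f"rigid fit needs >= 3 points, got {n}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # rank of the centered mobile set: < 2 means collinear/coincident points
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[0] > 0 and sv[1] / sv[0] < 1e-8:
        warnings.warn("collinear point set: rotation about the axis is unconstrained",
                      DegenerateGeometryWarning, stacklevel=2)
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


def apply_transform(t: RigidTransform, mol: Molecule) -> Molecule:
    """Apply a rigid transform to a molecule's coordinates; graph unchanged."""
    if not mol.has_coords:
        raise DataError(f"molecule {mol.id!r} has no coordinates")
    return mol.with_coords(t.apply(mol.coords))


def receptor_alignment(mobile: Receptor, reference: Receptor,
                       residue_filter: tuple[int, int] | None = None
                       ) -> tuple[RigidTransform, float, int]:
    """Kabsch fit of ``mobile`` C-alphas onto ``reference`` over common residues.

    Pairing is by (chain id, residue number) intersection; a sequence mismatch
    indicates a file problem and surfaces as :class:`PairingError`.
    ``residue_filter`` optionally restricts pairing to a residue-number range
    (inclusive), e.g. binding-site-only alignment.
    Returns (transform, fit_rmsd, n_pairs).
    """
    mob = dict(mobile.ca_atoms())
    ref = dict(reference.ca_atoms())
    common = sorted(set(mob) & set(ref))
    if residue_filter is not None:
        lo, hi = residue_filter
        common = [k for k in common if lo <= k[1] <= hi]
    if len(common) < 3:
        unmatched = sorted(set(mob) ^ set(ref))
        raise PairingError(
            f"only {len(common)} common C-alpha pairs (need >= 3); "
            f"unmatched residues: {unmatched[:20]}"
        )
    P = np.array([mob[k] for k in common])
    Q = np.array([ref[k] for k in common])
    transform, rmsd = kabsch_fit(P, Q)
    return transform, rmsd, len(common)


def align_complex(predicted_receptor: Receptor, reference_receptor: Receptor,
                  predicted_ligand: Molecule,
                  residue_filter: tuple[int, int] | None = None) -> Molecule:
    """Shift a predicted ligand into the reference receptor frame.

    Fits predicted C-alphas onto the reference C-alphas and applies the same
    transform to the ligand, mirroring how docked complexes are compared with
    crystallographic ones.
    """
    transform, _, _ = receptor_alignment(predicted_receptor, reference_receptor,
                                         residue_filter)
    return apply_transform(transform, predicted_ligand)
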