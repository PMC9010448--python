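"""Kabsch superposition and ligand transform propagation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fragchal import (Receptor, Residue, align_complex, apply_transform,
                      fixture_molecule, kabsch_fit, make_synthetic_receptor,
                      receptor_alignment)
from fragchal.errors import (DegenerateGeometryWarning, InsufficientPointsError,
                             PairingError)
from fragchal.superpose import RigidTransform


def _random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return RigidTransform(R, rng.normal(scale=5.0, size=3))


def _moved_receptor(receptor, transform):
    return Receptor([
        (cid, [Residue(r.name, r.seqnum,
                       {k: transform.apply(v) for k, v in r.atoms.items()})
               for r in residues])
        for cid, residues in receptor.chains
    ])


def test_identity_fit():
    X = np.random.default_rng(0).normal(size=(8, 3))
    t, rmsd = kabsch_fit(X, X)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(t.rotation, np.eye(3), atol=1e-10)
    assert np.allclose(t.translation, 0.0, atol=1e-10)


def test_exact_rigid_motion_is_recovered():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(10, 3))
    Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    Y = X @ Rz.T + np.array([1.0, 2.0, 3.0])
    t, rmsd = kabsch_fit(X, Y)
    assert rmsd == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(t.rotation, Rz, atol=1e-10)
    assert np.allclose(t.translation, [1.0, 2.0, 3.0], atol=1e-10)


def test_noisy_fit_matches_independent_implementation():
    """Minimized RMSD agrees with scipy's align_vectors on a 10-point set."""
    rng = np.random.default_rng(2)
    X = rng.normal(size=(10, 3))
    Y = X + rng.normal(scale=0.3, size=(10, 3))
    _, rmsd = kabsch_fit(X, Y)
    rot, rssd = Rotation.align_vectors(Y - Y.mean(0), X - X.mean(0))
    assert rmsd == pytest.approx(rssd / np.sqrt(10), abs=1e-2)
    # no sampled rotation does better: the fit is the global minimum
    Xc, Yc = X - X.mean(0), Y - Y.mean(0)
    for k in range(500):
        Rr = Rotation.random(random_state=np.random.RandomState(k)).as_matrix()
        trial = np.sqrt(np.mean(np.sum((Xc @ Rr.T - Yc) ** 2, axis=1)))
        assert trial >= rmsd - 1e-9


def test_fit_rmsd_is_symmetric_and_rigid_motion_invariant():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(12, 3))
    Y = X + rng.normal(scale=0.5, size=(12, 3))
    _, fwd = kabsch_fit(X, Y)
    _, bwd = kabsch_fit(Y, X)
    assert fwd == pytest.approx(bwd, abs=1e-9)
    T = _random_rigid(rng)
    _, moved = kabsch_fit(T.apply(X), T.apply(Y))
    assert moved == pytest.approx(fwd, abs=1e-9)


def test_reflection_branch_yields_proper_rotation():
    """Near-reflective inputs must still return det(R) = +1."""
    rng = np.random.default_rng(4)
    X = rng.normal(size=(6, 3))
    Y = X.copy()
    Y[:, 2] *= -1.0  # mirrored target
    t, _ = kabsch_fit(X, Y)
    assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)


def test_too_few_points_and_collinear_warning():
    with pytest.raises(InsufficientPointsError):
        kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.warns(DegenerateGeometryWarning):
        _, rmsd = kabsch_fit(line, line)
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_apply_transform_composition():
    mol = fixture_molecule("ethanol")
    rng = np.random.default_rng(5)
    t1, t2 = _random_rigid(rng), _random_rigid(rng)
    stepwise = apply_transform(t2, apply_transform(t1, mol))
    composed = apply_transform(t2.compose(t1), mol)
    assert np.allclose(stepwise.coords, composed.coords, atol=1e-9)
    ident = apply_transform(RigidTransform.identity(), mol)
    assert np.allclose(ident.coords, mol.coords)


def test_align_complex_cancels_rigid_displacement():
    receptor = make_synthetic_receptor(25)
    ligand = fixture_molecule("para_xylene")
    rng = np.random.default_rng(6)
    T = _random_rigid(rng)
    shifted = align_complex(_moved_receptor(receptor, T), receptor,
                            apply_transform(T, ligand))
    assert np.allclose(shifted.coords, ligand.coords, atol=1e-6)


def test_identical_receptors_leave_ligand_untouched():
    receptor = make_synthetic_receptor(25)
    ligand = fixture_molecule("ethanol")
    displaced = ligand.with_coords(ligand.coords + np.array([2.0, 0.0, 0.0]))
    out = align_complex(receptor, receptor, displaced)
    assert np.allclose(out.coords, displaced.coords, atol=1e-9)


def test_partial_residue_overlap_aligns_on_intersection():
    """30% residue mismatch: the fit must equal a manual fit on the
    intersected C-alpha set."""
    reference = make_synthetic_receptor(30, offset=1)
    mobile_full = make_synthetic_receptor(30, offset=10)  # residues 10..39
    rng = np.random.default_rng(7)
    T = _random_rigid(rng)
    mobile = _moved_receptor(mobile_full, T)
    transform, rmsd, n_pairs = receptor_alignment(mobile, reference)
    common = sorted(set(dict(mobile.ca_atoms())) & set(dict(reference.ca_atoms())))
    assert n_pairs == len(common) == 21
    mob_ca = dict(mobile.ca_atoms())
    ref_ca = dict(reference.ca_atoms())
    t2, rmsd2 = kabsch_fit(np.array([mob_ca[k] for k in common]),
                           np.array([ref_ca[k] for k in common]))
    assert rmsd == pytest.approx(rmsd2, abs=1e-12)
    assert np.allclose(transform.rotation, t2.rotation, atol=1e-9)


def test_insufficient_common_residues_raise_pairing_error():
    a = make_synthetic_receptor(10, offset=1)
    b = make_synthetic_receptor(10, offset=100)
    with pytest.raises(PairingError):
        receptor_alignment(a, b)
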