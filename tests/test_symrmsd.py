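"""Automorphism enumeration and symmetry-corrected RMSD."""

import itertools

import numpy as np
import pytest

from conftest import ORACLE_PANEL, brute_force_symmetry_rmsd
from fragchal import (fixture_molecule, molecule_with_random_coords,
                      naive_rmsd, parse_smiles, shuffle_atom_order,
                      symmetry_rmsd)
from fragchal.errors import DataError, GraphMismatchError, ResourceError
from fragchal.symrmsd import MolGraph, enumerate_automorphisms


def _graph(smiles):
    return MolGraph.from_molecule(parse_smiles(smiles, smiles))


def test_single_node_has_identity_only():
    assert enumerate_automorphisms(_graph("C")) == [(0,)]


def test_dimethyl_ether_end_swap():
    autos = enumerate_automorphisms(_graph("COC"))
    assert len(autos) == 2
    assert (0, 1, 2) in autos  # identity always present


def test_benzene_automorphisms_match_brute_force():
    g = _graph("c1ccccc1")
    autos = set(enumerate_automorphisms(g))
    brute = set()
    for perm in itertools.permutations(range(6)):
        if all((min(perm[i], perm[j]), max(perm[i], perm[j])) in g.edges
               for i, j in g.edges):
            brute.add(perm)
    assert autos == brute
    assert len(autos) == 12  # dihedral group of the hexagon


@pytest.mark.parametrize("smiles", ["c1ccccc1", "Cc1ccc(C)cc1", "C1CCNCC1",
                                    "CC(C)C", "c1cnccn1"])
def test_automorphism_group_matches_networkx(smiles):
    """Independent cross-check with networkx's VF2 matcher."""
    import networkx as nx
    from networkx.algorithms.isomorphism import GraphMatcher, categorical_node_match

    g = _graph(smiles)
    nxg = nx.Graph()
    for k, lab in enumerate(g.labels):
        nxg.add_node(k, element=lab)
    nxg.add_edges_from(g.edges)
    gm = GraphMatcher(nxg, nxg, node_match=categorical_node_match("element", None))
    nx_autos = {tuple(m[k] for k in range(g.n_nodes))
                for m in gm.isomorphisms_iter()}
    assert set(enumerate_automorphisms(g)) == nx_autos


def test_node_cap_raises_resource_error():
    with pytest.raises(ResourceError):
        enumerate_automorphisms(_graph("c1ccccc1"), node_cap=3)


def test_identical_molecules_give_zero_and_identity():
    mol = fixture_molecule("benzene")
    rmsd, sigma = symmetry_rmsd(mol, mol)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert sigma == tuple(range(6))


def test_symmetry_equivalent_swap_is_free():
    """Rotating benzene by one ring position moves every atom index but no
    atom position class: symmetric RMSD 0 where naive RMSD is large."""
    ref = fixture_molecule("benzene")
    rotated = ref.with_coords(np.roll(ref.coords, 1, axis=0))
    assert naive_rmsd(rotated, ref) > 1.0
    rmsd, _ = symmetry_rmsd(rotated, ref)
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_para_substituted_flip_is_free():
    """The two-fold flip of a para-disubstituted ring costs nothing."""
    ref = fixture_molecule("para_xylene")
    # flip: reverse ring orientation and swap the two methyls
    perm = [3, 2, 1, 0, 5, 4, 7, 6]
    flipped = ref.with_coords(ref.coords[perm])
    assert naive_rmsd(flipped, ref) > 1.0
    rmsd, _ = symmetry_rmsd(flipped, ref)
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_matches_exhaustive_oracle_on_panel():
    """Backtracking minimum equals the exhaustive-permutation minimum for
    randomized atom orders and noisy coordinates."""
    for k, smiles in enumerate(ORACLE_PANEL):
        ref = molecule_with_random_coords(smiles, f"ref{k}", seed=100 + k)
        shuffled, _ = shuffle_atom_order(ref, seed=200 + k)
        rng = np.random.default_rng(300 + k)
        pred = shuffled.with_coords(shuffled.coords
                                    + rng.normal(scale=0.5, size=(ref.heavy_atom_count, 3)))
        expected, _ = brute_force_symmetry_rmsd(pred, ref)
        got, _ = symmetry_rmsd(pred, ref)
        assert got == pytest.approx(expected, abs=1e-9), smiles


def test_symmetry_rmsd_invariant_under_atom_relabeling():
    ref = molecule_with_random_coords("Cc1ccc(C)cc1", "ref", seed=1)
    pred, _ = shuffle_atom_order(ref, seed=2)
    base, _ = symmetry_rmsd(pred, ref)
    for seed in range(3, 7):
        relabeled, _ = shuffle_atom_order(pred, seed=seed)
        rmsd, _ = symmetry_rmsd(relabeled, ref)
        assert rmsd == pytest.approx(base, abs=1e-9)


def test_trivial_automorphism_group_equals_naive():
    ref = molecule_with_random_coords("CCO", "ref", seed=4)
    rng = np.random.default_rng(5)
    pred = ref.with_coords(ref.coords + rng.normal(scale=0.3, size=(3, 3)))
    sym, sigma = symmetry_rmsd(pred, ref)
    assert sigma == (0, 1, 2)
    assert sym == pytest.approx(naive_rmsd(pred, ref), abs=1e-12)


def test_symmetry_never_exceeds_naive():
    for k, smiles in enumerate(["c1ccccc1", "COC", "Cc1ccc(C)cc1", "C1CCCCC1"]):
        ref = molecule_with_random_coords(smiles, "r", seed=k)
        rng = np.random.default_rng(50 + k)
        pred = ref.with_coords(ref.coords
                               + rng.normal(scale=1.0, size=ref.coords.shape))
        assert symmetry_rmsd(pred, ref)[0] <= naive_rmsd(pred, ref) + 1e-12


def test_graph_mismatch_names_element_differences():
    a = molecule_with_random_coords("CCO", "a", 0)
    b = molecule_with_random_coords("CCN", "b", 0)
    with pytest.raises(GraphMismatchError, match="element counts"):
        symmetry_rmsd(a, b)
    # same elements, different topology (e.g. ring vs chain) is also a mismatch
    c = molecule_with_random_coords("C1CCC1", "c", 0)
    d = molecule_with_random_coords("CCCC", "d", 0)
    with pytest.raises(GraphMismatchError, match="not isomorphic"):
        symmetry_rmsd(c, d)


def test_single_atom_displacement_naive_closed_form():
    a = molecule_with_random_coords("C", "a", 0)
    b = a.with_coords(a.coords + np.array([[2.0, 0.0, 0.0]]))
    assert naive_rmsd(b, a) == pytest.approx(2.0, abs=1e-12)
    with pytest.raises(DataError):
        naive_rmsd(a, molecule_with_random_coords("CC", "c", 0))
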