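import numpy as np
import pytest

from fragchal import build_ground_truth


@pytest.fixture(scope="session")
def kac_ground_truth():
    """799-fragment library with 47 hits and 40 exclusions (Kac-site shape)."""
    library = [f"F{i}" for i in range(1, 800)]
    hits = library[:47]
    excluded = library[47:87]
    return build_ground_truth(library, hits, excluded, site="kac")


@pytest.fixture(scope="session")
def all_sites_ground_truth():
    library = [f"F{i}" for i in range(1, 800)]
    return build_ground_truth(library, library[:52], library[52:92], site="all")


def brute_force_symmetry_rmsd(predicted, reference):
    """Exhaustive minimum RMSD over all label-preserving, edge-preserving
    bijections (permutations within element classes), independent of the
    backtracking search."""
    import itertools

    n = reference.heavy_atom_count
    ref_edges = {(min(b.i, b.j), max(b.i, b.j)) for b in reference.bonds}
    pred_edges = {(min(b.i, b.j), max(b.i, b.j)) for b in predicted.bonds}
    if len(ref_edges) != len(pred_edges):
        return None, None
    by_elem_ref = {}
    by_elem_pred = {}
    for k, a in enumerate(reference.atoms):
        by_elem_ref.setdefault(a.element, []).append(k)
    for k, a in enumerate(predicted.atoms):
        by_elem_pred.setdefault(a.element, []).append(k)
    if {e: len(v) for e, v in by_elem_ref.items()} != \
            {e: len(v) for e, v in by_elem_pred.items()}:
        return None, None
    elements = sorted(by_elem_ref)
    P = predicted.coords
    R = reference.coords
    best = None
    best_sigma = None
    pools = [itertools.permutations(by_elem_pred[e]) for e in elements]
    for combo in itertools.product(*pools):
        sigma = [0] * n
        for e, assignment in zip(elements, combo):
            for r_idx, p_idx in zip(by_elem_ref[e], assignment):
                sigma[r_idx] = p_idx
        ok = all((min(sigma[i], sigma[j]), max(sigma[i], sigma[j])) in pred_edges
                 for i, j in ref_edges)
        if not ok:
            continue
        d = P[sigma] - R
        rmsd = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
        sig = tuple(sigma)
        if best is None or rmsd < best or (rmsd == best and sig < best_sigma):
            best, best_sigma = rmsd, sig
    return best, best_sigma


# SMILES panel for oracle-equivalence checks: <= 10 heavy atoms, element-class
# sizes bounded so exhaustive permutation stays affordable
ORACLE_PANEL = [
    "c1ccccc1", "Cc1ccccc1", "Cc1ccc(C)cc1", "CCO", "COC",
    "c1ccncc1", "c1ccoc1", "c1ccsc1", "CC(C)C", "CC(C)(C)C",
    "OCC(O)CO", "NCCN", "C1CCCCC1", "C1CCNCC1", "c1cnccn1",
    "CC(=O)O", "FC(F)(F)C", "Clc1ccccc1", "NC(=O)C", "C1CC1",
]
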