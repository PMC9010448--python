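"""Molecular descriptors, circular-fingerprint similarity, rule-of-5.

Descriptor conventions (pinned so results are reproducible):

* molecular weight — sum of standard atomic masses including implicit H;
* logP — Wildman-Crippen atom contributions;
* TPSA — Ertl fragment contributions (A^2);
* HBD — N/O donors carrying at least one H;
* HBA — N/O acceptors excluding pyrrole-type and amide nitrogens;
* rotatable bonds — acyclic single bonds between non-terminal heavy atoms,
  amide C-N excluded (the strict convention);
* ring count — smallest set of smallest rings.

Similarity uses circular (Morgan) environments of radius 2 kept as a *set*
of hashed identifiers (count-insensitive), compared with the Tanimoto
coefficient |A intersect B| / |A union B|.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

from .chem import Molecule, to_rdkit
from .errors import ValidationError

DESCRIPTOR_FIELDS = ("molecular_weight", "logp", "tpsa", "hbd", "hba",
                     "rotatable_bonds", "ring_count", "heavy_atom_count")


@dataclass(frozen=True)
class DescriptorSet:
    molecular_weight: float
    logp: float
    tpsa: float
    hbd: int
    hba: int
    rotatable_bonds: int
    ring_count: int
    heavy_atom_count: int


def compute_descriptors(m: Molecule) -> DescriptorSet:
    rd = to_rdkit(m)
    return DescriptorSet(
        molecular_weight=float(Descriptors.MolWt(rd)),
        logp=float(Crippen.MolLogP(rd)),
        tpsa=float(rdMolDescriptors.CalcTPSA(rd)),
        hbd=int(rdMolDescriptors.CalcNumHBD(rd)),
        hba=int(rdMolDescriptors.CalcNumHBA(rd)),
        rotatable_bonds=int(rdMolDescriptors.CalcNumRotatableBonds(rd)),
        ring_count=int(rdMolDescriptors.CalcNumRings(rd)),
        heavy_atom_count=int(rd.GetNumHeavyAtoms()),
    )


@dataclass(frozen=True)
class Fingerprint:
    """Radius-2 circular fingerprint as a set of hashed environment ids."""

    radius: int
    bits: frozenset[int]


def morgan_fingerprint(m: Molecule, radius: int = 2) -> Fingerprint:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    sfp = gen.GetSparseCountFingerprint(to_rdkit(m))
    return Fingerprint(radius, frozenset(sfp.GetNonzeroElements()))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Set Tanimoto coefficient; defined as 1 when both bit sets are empty."""
    if a.radius != b.radius:
        raise ValidationError(f"fingerprint radii differ: {a.radius} vs {b.radius}")
    if not a.bits and not b.bits:
        return 1.0
    return len(a.bits & b.bits) / len(a.bits | b.bits)


RULE_OF_FIVE_LIMITS = {"molecular_weight": 500.0, "logp": 5.0, "hbd": 5, "hba": 10}


def rule_of_five(d: DescriptorSet, strict: bool = False) -> tuple[bool, list[str]]:
    """Lipinski compliance: classic mode allows one violation, strict allows none."""
    violations = [f"{name} > {limit}" for name, limit in RULE_OF_FIVE_LIMITS.items()
                  if getattr(d, name) > limit]
    allowed = 0 if strict else 1
    return len(violations) <= allowed, violations


def _cohort_stats(cohort: list[DescriptorSet], name: str) -> dict[str, float]:
    v = np.array([getattr(d, name) for d in cohort], dtype=float)
    return {"mean": float(v.mean()), "median": float(np.median(v)),
            "min": float(v.min()), "max": float(v.max())}


def cohort_compare(set_a: list[DescriptorSet], set_b: list[DescriptorSet]
                   ) -> pd.DataFrame:
    """Per-descriptor summary of two cohorts and the difference of means (b - a).

    Used to quantify how follow-up suggestions drift from the fragment-hit
    cohort (typically: every count rises along with molecular weight).
    """
    if not set_a or not set_b:
        raise ValidationError("both cohorts must be non-empty")
    rows = {}
    for name in DESCRIPTOR_FIELDS:
        sa = _cohort_stats(set_a, name)
        sb = _cohort_stats(set_b, name)
        row = {f"{k}_a": v for k, v in sa.items()}
        row.update({f"{k}_b": v for k, v in sb.items()})
        row["diff_mean"] = sb["mean"] - sa["mean"]
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def pairwise_tanimoto_summary(fps: list[Fingerprint]) -> dict[str, float]:
    """Distribution summary of all pairwise Tanimoto coefficients in a cohort."""
    if not fps:
        raise ValidationError("empty fingerprint cohort")
    values = [tanimoto(a, b) for a, b in itertools.combinations(fps, 2)]
    if not values:
        return {"mean": float("nan"), "median": float("nan"),
                "min": float("nan"), "max": float("nan"), "n_pairs": 0}
    v = np.asarray(values)
    return {"mean": float(v.mean()), "median": float(np.median(v)),
            "min": float(v.min()), "max": float(v.max()), "n_pairs": int(v.size)}


def cross_tanimoto_summary(fps_a: list[Fingerprint], fps_b: list[Fingerprint]
                           ) -> dict[str, float]:
    """Summary of Tanimoto coefficients across two cohorts (all a x b pairs)."""
    if not fps_a or not fps_b:
        raise ValidationError("both fingerprint cohorts must be non-empty")
    v = np.asarray([tanimoto(a, b) for a in fps_a for b in fps_b])
    return {"mean": float(v.mean()), "median": float(np.median(v)),
            "min": float(v.min()), "max": float(v.max()), "n_pairs": int(v.size)}


def descriptor_table(mols: list[Molecule]) -> pd.DataFrame:
    """One descriptor row per molecule, indexed by molecule id."""
    data = {m.id: vars(compute_descriptors(m)) for m in mols}
    return pd.DataFrame.from_dict(data, orient="index")[list(DESCRIPTOR_FIELDS)]
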