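"""Ranked-pose evaluation: per-fragment RMSDs and success-rate curves.

Each fragment's submission is 1-5 ranked poses. A pose succeeds when its
symmetry-corrected heavy-atom RMSD to the crystallographic pose is at or
below the cutoff (2.0 A by default; the comparison is inclusive and
configurable). Two summary rates are tracked: *top-1* scores only the
best-ranked pose, *best-in-all* scores the lowest-RMSD pose among those
submitted — their gap measures how often the scoring function ranked a good
pose below a worse one.

Poses whose heavy-atom graph cannot be mapped onto the reference (wrong
tautomer, wrong molecule) are excluded from that fragment's RMSD list and
recorded as errors; a fragment with no evaluable pose counts as a failure in
the denominator, so a submission cannot improve by submitting unscoreable
files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import Molecule, Receptor
from .errors import FragchalError, GraphMismatchError, ValidationError
from .superpose import align_complex
from .symrmsd import symmetry_rmsd

MAX_POSES = 5
DEFAULT_CUTOFF = 2.0


@dataclass
class PoseSet:
    """One fragment's evaluation unit: reference pose plus ranked predictions.

    Receptors are optional; when both are given every predicted pose is first
    shifted into the reference frame via C-alpha alignment. Without receptors
    the coordinates are taken to share a frame already.
    """

    fragment_id: str
    reference: Molecule
    predicted: list[Molecule]
    predicted_receptor: Receptor | None = None
    reference_receptor: Receptor | None = None

    def __post_init__(self) -> None:
        if not (1 <= len(self.predicted) <= MAX_POSES):
            raise ValidationError(
                f"fragment {self.fragment_id!r}: {len(self.predicted)} poses "
                f"(need 1..{MAX_POSES})"
            )


@dataclass
class PoseEvalRow:
    """Per-fragment result: RMSD per rank and success flags at one cutoff."""

    fragment_id: str
    rmsd_by_rank: list[float]  # NaN for poses that failed isomorphism
    cutoff: float
    pose_errors: list[str] = field(default_factory=list)

    @property
    def evaluable(self) -> bool:
        return any(math.isfinite(r) for r in self.rmsd_by_rank)

    @property
    def top1_rmsd(self) -> float:
        return self.rmsd_by_rank[0]

    @property
    def best_rmsd(self) -> float:
        finite = [r for r in self.rmsd_by_rank if math.isfinite(r)]
        return min(finite) if finite else math.nan

    @property
    def top1_success(self) -> bool:
        return math.isfinite(self.top1_rmsd) and self.top1_rmsd <= self.cutoff

    @property
    def best_success(self) -> bool:
        return self.evaluable and self.best_rmsd <= self.cutoff


def evaluate_pose_set(ps: PoseSet, cutoff: float = DEFAULT_CUTOFF) -> PoseEvalRow:
    """Align (if receptors are present) and score every pose of one fragment."""
    rmsds: list[float] = []
    errors: list[str] = []
    for rank, pose in enumerate(ps.predicted, start=1):
        try:
            ligand = pose
            if ps.predicted_receptor is not None and ps.reference_receptor is not None:
                ligand = align_complex(ps.predicted_receptor, ps.reference_receptor,
                                       pose)
            rmsd, _ = symmetry_rmsd(ligand, ps.reference)
            rmsds.append(rmsd)
        except (GraphMismatchError, FragchalError) as exc:
            rmsds.append(math.nan)
            errors.append(f"rank {rank}: {exc}")
    return PoseEvalRow(ps.fragment_id, rmsds, cutoff, errors)


def success_rates(rows: list[PoseEvalRow], cutoff: float | None = None,
                  denominator: int | None = None) -> tuple[float, float]:
    """(top-1 rate, best-in-all rate) over a set of fragments.

    ``denominator`` defaults to the number of rows; pass the full stage size
    (e.g. 47) to score a submission that skipped fragments against the whole
    task. Fragments with no evaluable pose count as failures.
    """
    if not rows:
        raise ValidationError("no pose-evaluation rows")
    denom = denominator if denominator is not None else len(rows)
    if denom < len(rows):
        raise ValidationError("denominator smaller than the number of rows")
    if cutoff is None:
        top1 = sum(r.top1_success for r in rows)
        best = sum(r.best_success for r in rows)
    else:
        top1 = sum(1 for r in rows
                   if math.isfinite(r.top1_rmsd) and r.top1_rmsd <= cutoff)
        best = sum(1 for r in rows
                   if r.evaluable and r.best_rmsd <= cutoff)
    return top1 / denom, best / denom


@dataclass
class SuccessCurve:
    """Success rate as a step function of the RMSD cutoff."""

    cutoffs: np.ndarray
    top1_rate: np.ndarray
    best_rate: np.ndarray


def success_curve(rows: list[PoseEvalRow], cutoff_grid: np.ndarray,
                  denominator: int | None = None) -> SuccessCurve:
    """Evaluate both success rates on a strictly increasing cutoff grid."""
    grid = np.asarray(cutoff_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValidationError("cutoff grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("cutoff grid must be strictly increasing")
    top1 = np.empty(grid.size)
    best = np.empty(grid.size)
    for k, c in enumerate(grid):
        top1[k], best[k] = success_rates(rows, cutoff=float(c),
                                         denominator=denominator)
    return SuccessCurve(grid, top1, best)
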