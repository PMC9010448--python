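"""Binder/non-binder screening evaluation.

Crystallographic screening yields, per fragment, one of three outcomes: a
*hit* (interpretable ligand density), a *miss* (usable diffraction data, no
density), or *excluded* (no usable diffraction data — these fragments carry
no information and are dropped before any metric is computed). Submissions
are Boolean binder calls, so the evaluation reduces to the 2x2 confusion
table. Because the library is dominated by non-binders, performance is
summarized by balanced accuracy, the plain mean of sensitivity (true-positive
rate) and specificity (true-negative rate); 0.5 is the random line.

Uncertainty is quantified with the percentile bootstrap: resample the
(prediction, label) pairs with replacement, recompute the metric, and take
the 2.5th/97.5th percentiles of the resample distribution. A with-replacement
resample of paired binary arrays is fully described by its four confusion
cell counts, so the resampling is drawn directly as a multinomial over
(TP, FN, TN, FP) — exactly equivalent to index resampling, and vectorizable.
Resamples that draw no positives (or no negatives) leave the corresponding
rate undefined; they are discarded and counted rather than imputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chem import SubmissionRecordS1
from .errors import DegenerateDataError, FormatError, ValidationError


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    EXCLUDED = "excluded"


_CSV_LABELS = {"hit": Label.POSITIVE, "miss": Label.NEGATIVE, "no_data": Label.EXCLUDED}
_LABELS_CSV = {v: k for k, v in _CSV_LABELS.items()}


@dataclass
class GroundTruth:
    """Per-fragment crystallographic outcome at one binding site."""

    site: str
    labels: dict[str, Label]

    def _count(self, label: Label) -> int:
        return sum(1 for v in self.labels.values() if v is label)

    @property
    def n_positive(self) -> int:
        return self._count(Label.POSITIVE)

    @property
    def n_negative(self) -> int:
        return self._count(Label.NEGATIVE)

    @property
    def n_excluded(self) -> int:
        return self._count(Label.EXCLUDED)

    @property
    def non_excluded_ids(self) -> list[str]:
        return sorted(k for k, v in self.labels.items() if v is not Label.EXCLUDED)


def build_ground_truth(library: Sequence[str], hits: Iterable[str],
                       excluded: Iterable[str], site: str = "all") -> GroundTruth:
    """Label a fragment library: hits -> positive, excluded -> excluded,
    remainder -> negative."""
    lib = list(library)
    lib_set = set(lib)
    if len(lib_set) != len(lib):
        raise ValidationError("library contains duplicate fragment ids")
    hits = set(hits)
    excluded = set(excluded)
    unknown = sorted((hits | excluded) - lib_set)
    if unknown:
        raise ValidationError(f"ids not in library: {unknown}")
    overlap = sorted(hits & excluded)
    if overlap:
        raise ValidationError(f"ids both hit and excluded: {overlap}")
    labels = {}
    for fid in lib:
        if fid in hits:
            labels[fid] = Label.POSITIVE
        elif fid in excluded:
            labels[fid] = Label.EXCLUDED
        else:
            labels[fid] = Label.NEGATIVE
    return GroundTruth(site, labels)


def read_ground_truth_csv(path: str | Path, site: str = "all") -> GroundTruth:
    """Read a ground-truth CSV with columns fragment_id, label {hit,miss,no_data}."""
    labels: dict[str, Label] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty ground-truth file") from None
        for rowno, row in enumerate(reader, start=2):
            if not row or not any(c.strip() for c in row):
                continue
            fid, raw = row[0].strip(), row[1].strip()
            if fid in labels:
                raise ValidationError(f"{path}:{rowno}: duplicate fragment id {fid!r}")
            if raw not in _CSV_LABELS:
                raise ValidationError(
                    f"{path}:{rowno}: unknown label {raw!r} "
                    f"(allowed: hit, miss, no_data)"
                )
            labels[fid] = _CSV_LABELS[raw]
    if not labels:
        raise FormatError(f"{path}: no ground-truth rows")
    return GroundTruth(site, labels)


def write_ground_truth_csv(gt: GroundTruth, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fragment_id", "label"])
        for fid in sorted(gt.labels):
            writer.writerow([fid, _LABELS_CSV[gt.labels[fid]]])


def hit_rate(n_hits: int, n_library: int) -> float:
    """Screening hit rate as a percentage, reported to 2 decimals."""
    if n_library <= 0:
        raise ValidationError("library size must be positive")
    if not (0 <= n_hits <= n_library):
        raise ValidationError(f"hit count {n_hits} outside [0, {n_library}]")
    return round(100.0 * n_hits / n_library, 2)


@dataclass(frozen=True)
class ClassificationMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None


def _confusion(submission: Sequence[SubmissionRecordS1], gt: GroundTruth
               ) -> tuple[int, int, int, int]:
    preds: dict[str, bool] = {}
    for rec in submission:
        if rec.fragment_id in preds:
            raise ValidationError(f"duplicate prediction for {rec.fragment_id!r}")
        preds[rec.fragment_id] = rec.predicted_binder
    missing = [fid for fid in gt.non_excluded_ids if fid not in preds]
    if missing:
        raise ValidationError(f"missing predictions for: {missing[:20]}"
                              + (" ..." if len(missing) > 20 else ""))
    tp = fp = tn = fn = 0
    for fid, label in gt.labels.items():
        if label is Label.EXCLUDED:
            continue  # excluded fragments never influence any metric
        p = preds[fid]
        if label is Label.POSITIVE:
            tp, fn = tp + p, fn + (not p)
        else:
            fp, tn = fp + p, tn + (not p)
    return tp, fp, tn, fn


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> ClassificationMetrics:
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    ba = (sens + spec) / 2 if (sens is not None and spec is not None) else None
    return ClassificationMetrics(tp, fp, tn, fn, sens, spec, ba)


def evaluate_stage1(submission: Sequence[SubmissionRecordS1],
                    gt: GroundTruth) -> ClassificationMetrics:
    """Confusion metrics of a Boolean screening submission against ground truth.

    Excluded fragments are dropped before scoring. If the ground truth has no
    positives (or no negatives) the undefined rate — and balanced accuracy —
    are reported as ``None``.
    """
    return metrics_from_confusion(*_confusion(submission, gt))


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile-bootstrap confidence interval for one screening metric."""

    metric: str
    point: float
    lower: float
    upper: float
    level: float
    n_resamples: int
    seed: int
    n_discarded: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError("bootstrap CI has lower > upper")


_METRICS = ("sensitivity", "specificity", "balanced_accuracy")


def bootstrap_ci(submission: Sequence[SubmissionRecordS1], gt: GroundTruth,
                 metric: str = "balanced_accuracy", n_resamples: int = 10000,
                 level: float = 0.95, seed: int = 0) -> BootstrapCI:
    """Percentile bootstrap CI from joint (prediction, label) pair resampling."""
    if metric not in _METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {_METRICS}")
    tp, fp, tn, fn = _confusion(submission, gt)
    point = getattr(metrics_from_confusion(tp, fp, tn, fn), metric)
    if point is None:
        raise DegenerateDataError(
            f"{metric} undefined on the full data (no positives or negatives)"
        )
    n = tp + fp + tn + fn
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, [tp / n, fn / n, tn / n, fp / n], size=n_resamples)
    btp, bfn, btn, bfp = (counts[:, k].astype(float) for k in range(4))
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = btp / (btp + bfn)
        spec = btn / (btn + bfp)
    if metric == "sensitivity":
        values, valid = sens, (btp + bfn) > 0
    elif metric == "specificity":
        values, valid = spec, (btn + bfp) > 0
    else:
        valid = ((btp + bfn) > 0) & ((btn + bfp) > 0)
        values = (sens + spec) / 2
    n_discarded = int(n_resamples - valid.sum())
    if not valid.any():
        raise DegenerateDataError("every bootstrap resample left the metric undefined")
    alpha = (1.0 - level) / 2.0
    lower, upper = np.percentile(values[valid], [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(metric, float(point), float(lower), float(upper),
                       level, n_resamples, seed, n_discarded)


def random_null_submission(gt: GroundTruth, p_binder: float, seed: int = 0
                           ) -> list[SubmissionRecordS1]:
    """Label-independent random predictor (the challenge's null baseline)."""
    if not (0.0 <= p_binder <= 1.0):
        raise ValidationError(f"p_binder {p_binder} outside [0, 1]")
    rng = np.random.default_rng(seed)
    ids = gt.non_excluded_ids
    draws = rng.random(len(ids)) < p_binder
    return [SubmissionRecordS1(fid, bool(d)) for fid, d in zip(ids, draws)]


def summarize_balanced_accuracies(values: Sequence[float]) -> dict[str, float]:
    """Cross-submission summary: mean with SD and SEM, each labeled.

    Emitted together because 'mean +/- x' summaries are ambiguous about which
    spread x denotes.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("no balanced accuracies to summarize")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return {"mean": float(v.mean()), "sd": sd,
            "sem": sd / np.sqrt(v.size) if v.size > 1 else 0.0,
            "n": int(v.size)}
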