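"""Threshold calibration from positive and negative training sets.

The (quality, superiority) cutoff pair is chosen by exhaustive search over
the achievable decision boundaries: for each axis the candidate cutoffs are
the midpoints between consecutive distinct observed values plus sentinels
below the minimum and at the maximum, which together realize every
classification a threshold on that axis can produce.  All cutoff pairs are
evaluated; the pair minimizing total training error (false accepts + false
rejects) wins, ties broken first by maximal margin (the minimum distance
from any training point's scores to either cutoff line) and then by the
smallest thresholds.  The chosen pair is verified by stratified N-fold
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .scoring import Thresholds, decide

Label = Literal["positive", "negative"]


@dataclass(frozen=True)
class TrainingPoint:
    id: str
    quality: float
    superiority: float
    label: Label

    def __post_init__(self) -> None:
        if not (np.isfinite(self.quality) and np.isfinite(self.superiority)):
            raise ValueError(f"non-finite scores for training point {self.id!r}")
        if self.label not in ("positive", "negative"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class TuneResult:
    thresholds: Thresholds
    false_accepts: int
    false_rejects: int
    margin: float

    @property
    def total_errors(self) -> int:
        return self.false_accepts + self.false_rejects

    @property
    def zero_error(self) -> bool:
        return self.total_errors == 0


def _candidate_cutoffs(values: Sequence[float]) -> List[float]:
    """Midpoints between consecutive distinct values plus outer sentinels.

    With a strict ``>`` decision the sentinel below the minimum accepts
    every point on that axis and the maximum itself accepts none.
    """
    distinct = sorted({float(v) for v in values})
    cutoffs = [distinct[0] - 1.0]
    cutoffs += [(a + b) / 2.0 for a, b in zip(distinct, distinct[1:])]
    cutoffs.append(distinct[-1])
    return cutoffs


def _count_errors(
    q: np.ndarray, s: np.ndarray, is_pos: np.ndarray, qmin: float, smin: float
) -> Tuple[int, int]:
    accepted = (q > qmin) & (s > smin)
    false_accepts = int(np.count_nonzero(accepted & ~is_pos))
    false_rejects = int(np.count_nonzero(~accepted & is_pos))
    return false_accepts, false_rejects


def _margin(q: np.ndarray, s: np.ndarray, qmin: float, smin: float) -> float:
    # per-axis margin: both cutoff lines stay maximally clear of every
    # observed score, so on separable data the corner lands mid-gap on
    # both axes
    per_axis = np.minimum(np.abs(q - qmin), np.abs(s - smin))
    return float(per_axis.min())


def grid_search(points: Sequence[TrainingPoint]) -> TuneResult:
    """Exhaustive search of the achievable (quality, superiority) cutoffs.

    Requires at least one point of each label.  The decision rule matches
    the classifier's (strict ``>`` on both axes).
    """
    labels = {p.label for p in points}
    if labels != {"positive", "negative"}:
        raise ValueError("training set must contain both positive and negative points")
    q = np.array([p.quality for p in points])
    s = np.array([p.superiority for p in points])
    is_pos = np.array([p.label == "positive" for p in points])

    best: Optional[Tuple[int, float, float, float, int, int]] = None
    for qmin in _candidate_cutoffs(q):
        for smin in _candidate_cutoffs(s):
            fa, fr = _count_errors(q, s, is_pos, qmin, smin)
            margin = _margin(q, s, qmin, smin)
            # sort key: fewest errors, then largest margin, then smallest
            # thresholds (lexicographic)
            key = (fa + fr, -margin, qmin, smin, fa, fr)
            if best is None or key < best:
                best = key
    assert best is not None
    total, neg_margin, qmin, smin, fa, fr = best
    return TuneResult(
        thresholds=Thresholds(qmin, smin, "tuned"),
        false_accepts=fa,
        false_rejects=fr,
        margin=-neg_margin,
    )


@dataclass
class FoldResult:
    fold: int
    thresholds: Thresholds
    held_out_false_accepts: int
    held_out_false_rejects: int
    held_out_size: int

    @property
    def error_rate(self) -> float:
        errors = self.held_out_false_accepts + self.held_out_false_rejects
        return errors / self.held_out_size if self.held_out_size else 0.0


@dataclass
class CrossValidationResult:
    folds: List[FoldResult]

    @property
    def mean_error_rate(self) -> float:
        return float(np.mean([f.error_rate for f in self.folds]))


def _stratified_folds(
    points: Sequence[TrainingPoint], n_folds: int, seed: int
) -> List[List[int]]:
    rng = np.random.default_rng(seed)
    folds: List[List[int]] = [[] for _ in range(n_folds)]
    for label in ("positive", "negative"):
        idx = [i for i, p in enumerate(points) if p.label == label]
        rng.shuffle(idx)
        for rank, i in enumerate(idx):
            folds[rank % n_folds].append(i)
    return folds


def cross_validate(
    points: Sequence[TrainingPoint], n_folds: int = 10, seed: int = 0
) -> CrossValidationResult:
    """Stratified shuffled N-fold cross-validation of the tuned thresholds.

    Per fold: tune on the training folds, count held-out errors under the
    classifier's decision rule.  Deterministic given the seed.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    for label in ("positive", "negative"):
        n_label = sum(1 for p in points if p.label == label)
        if n_folds > n_label:
            raise ValueError(
                f"n_folds={n_folds} exceeds the {n_label} {label} points"
            )
    folds = _stratified_folds(points, n_folds, seed)
    results: List[FoldResult] = []
    for fold_no, held_out_idx in enumerate(folds):
        held_out = set(held_out_idx)
        train = [p for i, p in enumerate(points) if i not in held_out]
        tuned = grid_search(train)
        fa = fr = 0
        for i in held_out_idx:
            p = points[i]
            d = decide(p.quality, p.superiority, tuned.thresholds)
            if d.accepted and p.label == "negative":
                fa += 1
            elif not d.accepted and p.label == "positive":
                fr += 1
        results.append(
            FoldResult(fold_no, tuned.thresholds, fa, fr, len(held_out_idx))
        )
    return CrossValidationResult(folds=results)


def read_training_points(path) -> List[TrainingPoint]:
    """Read a TSV of (id, quality, superiority, label) training points."""
    points = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            points.append(
                TrainingPoint(
                    fields[0], float(fields[1]), float(fields[2]),
                    fields[3].strip().lower(),  # type: ignore[arg-type]
                )
            )
    return points
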