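"""Diversity-maximizing representative selection.

The sensitivity phase needs a small set of query sequences spanning the
target gene's diversity.  Given a per-group (e.g. per-phylum) sequence
collection, this module selects k representatives with approximately
maximum mutual p-distance by simulated annealing over size-k subsets.

p-distance is the proportion of differing positions between two aligned
sequences, computed over columns where neither sequence has a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Literal, Sequence, Tuple

import numpy as np
from Bio import Align

GAP_CHARS = frozenset("-.")

ObjectiveMode = Literal["sum", "maximin"]


def p_distance(a: str, b: str) -> float:
    """Proportion of comparable (both non-gap) columns where a and b differ.

    Sequences must be pre-aligned (equal length).  Returns 0 when no
    column is comparable.  Case-insensitive.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    comparable = 0
    diffs = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        comparable += 1
        if x != y:
            diffs += 1
    return diffs / comparable if comparable else 0.0


def pairwise_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Tuple[str, str]:
    """Global pairwise alignment under simple match/mismatch/gap scores.

    Deterministic: of the co-optimal alignments the first in the aligner's
    canonical order is returned.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def aligned_p_distance(a: str, b: str, **align_kwargs) -> float:
    """p-distance of two unaligned sequences after global alignment."""
    aligned_a, aligned_b = pairwise_align(a, b, **align_kwargs)
    return p_distance(aligned_a, aligned_b)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of p-distances in [0, 1] over named sequences."""

    ids: List[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal in distance matrix")
        if self.d.min() < 0 or self.d.max() > 1:
            raise ValueError("p-distances must lie in [0, 1]")
        self._index = {sid: i for i, sid in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate sequence ids")

    @classmethod
    def from_sequences(
        cls, named_seqs: Sequence[Tuple[str, str]], **align_kwargs
    ) -> "DistanceMatrix":
        """All-pairs p-distance matrix from unaligned sequences."""
        ids = [name for name, _ in named_seqs]
        n = len(ids)
        d = np.zeros((n, n))
        for i, j in combinations(range(n), 2):
            d[i, j] = d[j, i] = aligned_p_distance(
                named_seqs[i][1], named_seqs[j][1], **align_kwargs
            )
        return cls(ids=ids, d=d)

    def index(self, sid: str) -> int:
        return self._index[sid]


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule for the subset annealer."""

    t_start: float = 1.0
    t_end: float = 1e-4
    cooling: float = 0.95
    steps_per_temp: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_start <= 0 or self.t_end <= 0:
            raise ValueError("temperatures must be positive")
        if self.t_end >= self.t_start:
            raise ValueError("t_end must be below t_start")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must lie in (0, 1)")
        if self.steps_per_temp < 1:
            raise ValueError("steps_per_temp must be positive")


def subset_objective(
    subset: Sequence[str], m: DistanceMatrix, mode: ObjectiveMode = "sum"
) -> float:
    """Diversity objective of a subset: sum (default) or minimum of its
    pairwise distances."""
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 ids")
    if len(set(subset)) != len(subset):
        raise ValueError("subset contains duplicate ids")
    idx = [m.index(s) for s in subset]
    pairs = [m.d[i, j] for i, j in combinations(idx, 2)]
    if mode == "sum":
        return float(sum(pairs))
    if mode == "maximin":
        return float(min(pairs))
    raise ValueError(f"unknown objective mode {mode!r}")


def anneal_select(
    m: DistanceMatrix,
    k: int,
    sched: AnnealSchedule = AnnealSchedule(),
    mode: ObjectiveMode = "sum",
) -> Tuple[List[str], List[float]]:
    """Select k ids of approximately maximum mutual distance.

    State: a size-k subset.  Move: swap one member with one non-member,
    both chosen uniformly.  Improving moves are always accepted; a
    worsening move with objective change delta < 0 is accepted with
    probability exp(delta / T).  Temperature cools geometrically from
    ``t_start`` to ``t_end``.  Returns the best-ever subset (in the
    matrix's id order) and the per-temperature trace of the best objective.
    Fully reproducible given the schedule's seed.
    """
    n = len(m.ids)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds population size {n}")
    if k == n:
        return list(m.ids), [subset_objective(m.ids, m, mode)]

    rng = np.random.default_rng(sched.seed)
    current = list(rng.choice(n, size=k, replace=False))
    current_obj = _objective_idx(current, m.d, mode)
    best = list(current)
    best_obj = current_obj
    trace: List[float] = []

    t = sched.t_start
    while t > sched.t_end:
        for _ in range(sched.steps_per_temp):
            inside = int(rng.integers(k))
            outside_pool = [i for i in range(n) if i not in current]
            outside = outside_pool[int(rng.integers(len(outside_pool)))]
            proposal = list(current)
            proposal[inside] = outside
            proposal_obj = _objective_idx(proposal, m.d, mode)
            delta = proposal_obj - current_obj
            if delta >= 0 or rng.random() < np.exp(delta / t):
                current, current_obj = proposal, proposal_obj
                if current_obj > best_obj:
                    best, best_obj = list(current), current_obj
        trace.append(best_obj)
        t *= sched.cooling
    best_ids = [m.ids[i] for i in sorted(best)]
    return best_ids, trace


def _objective_idx(idx: Sequence[int], d: np.ndarray, mode: ObjectiveMode) -> float:
    sub = d[np.ix_(idx, idx)]
    if mode == "sum":
        return float(sub.sum() / 2.0)
    upper = sub[np.triu_indices(len(idx), k=1)]
    return float(upper.min())


def brute_force_select(
    m: DistanceMatrix, k: int, mode: ObjectiveMode = "sum"
) -> Tuple[List[str], float]:
    """Exhaustive optimum over all size-k subsets (small instances only)."""
    best_subset: List[str] | None = None
    best_obj = -np.inf
    for combo in combinations(range(len(m.ids)), k):
        obj = _objective_idx(list(combo), m.d, mode)
        if obj > best_obj:
            best_obj = obj
            best_subset = [m.ids[i] for i in combo]
    assert best_subset is not None
    return best_subset, float(best_obj)
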