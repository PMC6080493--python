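"""Quality and superiority statistics and the accept/reject decision.

The miner classifies candidate protein sequences in two phases, each driven
by a single statistic derived from search E-values:

* **quality** (sensitivity phase) — the negative log-10 of the smallest
  E-value among all homology-search hits from the representative queries to
  a subject sequence.  A subject hit by two queries at E = 1.0e-50 and
  1.0e-40 has quality 50.

* **superiority** (specificity phase) — the negative log-10 E-value of the
  best match to a conserved domain diagnostic of the target gene, minus the
  negative log-10 E-value of the best match to a conserved domain of a
  different gene.  A candidate matching a target-gene domain at 1.0e-70 and
  an off-target domain at 1.0e-65 has superiority 5.

A candidate is accepted when both statistics exceed their thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

#: Score assigned to an E-value of exactly 0 (or one that underflows):
#: bounded, and larger than any plausible threshold.
DEFAULT_SCORE_CAP = 300.0

DomainClass = Literal["positive", "negative", "uninformative"]


def evalue_score(e_value: float, score_cap: float = DEFAULT_SCORE_CAP) -> float:
    """Map an E-value to its non-negative -log10 score.

    E-values above 1 clamp to 0 (scores never go negative); an E-value of 0
    or one whose log underflows clamps to ``score_cap``.
    """
    if e_value < 0:
        raise ValueError(f"E-value must be non-negative, got {e_value}")
    if e_value == 0:
        return score_cap
    score = -math.log10(e_value)
    return float(min(max(score, 0.0), score_cap))


@dataclass(frozen=True)
class Quality:
    """Sensitivity statistic for one subject sequence."""

    subject_id: str
    score: float
    best_query_id: str


@dataclass(frozen=True)
class Superiority:
    """Specificity statistic for one candidate sequence."""

    candidate_id: str
    score: float
    best_positive_domain: Optional[str] = None
    best_negative_domain: Optional[str] = None


@dataclass(frozen=True)
class Thresholds:
    """A (quality, superiority) cutoff pair.

    The strict pair (0.9, 5) is the operating point; the relaxed pair
    (0, -20) is used only to enumerate near-miss sequences for
    false-negative estimation.
    """

    quality_min: float
    superiority_min: float
    label: str = "custom"

    @classmethod
    def strict(cls) -> "Thresholds":
        return cls(0.9, 5.0, "strict")

    @classmethod
    def relaxed(cls) -> "Thresholds":
        return cls(0.0, -20.0, "relaxed")


@dataclass(frozen=True)
class Decision:
    accepted: bool
    #: "ok" when accepted; otherwise the first failed test
    #: ("quality" before "superiority").
    reason: str


class SubjectAbsentError(KeyError):
    """Raised when quality is requested for a subject with no hits."""


def compute_quality(
    hits: Iterable[Tuple[str, str, float]],
    subject_id: str,
    score_cap: float = DEFAULT_SCORE_CAP,
) -> Quality:
    """Quality of ``subject_id`` over ``(query_id, subject_id, e_value)`` hits.

    The score is the maximum of ``-log10(E)`` over all hits to the subject,
    clamped to ``[0, score_cap]``.  ``best_query_id`` is the query of the
    minimal-E hit; ties break to the lexicographically smallest query id.
    Hit order and duplicate hits do not affect the result.
    """
    best: Optional[Tuple[float, str]] = None
    for query_id, subj, e_value in hits:
        if subj != subject_id:
            continue
        if e_value < 0:
            raise ValueError(f"negative E-value {e_value} for hit {query_id}->{subj}")
        key = (e_value, query_id)
        if best is None or key < best:
            best = key
    if best is None:
        raise SubjectAbsentError(f"no hits to subject {subject_id!r}")
    e_value, query_id = best
    return Quality(subject_id, evalue_score(e_value, score_cap), query_id)


def compute_superiority(
    domain_hits: Iterable[Tuple[str, float]],
    class_map: Mapping[str, DomainClass],
    candidate_id: str = "",
    score_cap: float = DEFAULT_SCORE_CAP,
    missing_evalue: float = 1.0,
) -> Superiority:
    """Superiority of a candidate over its ``(domain_id, e_value)`` hits.

    Each side of the difference is the score of the best (minimal-E) hit to
    a domain of that class; a class with no match contributes
    ``evalue_score(missing_evalue)`` (0 by default).  Uninformative domains
    never contribute; domains absent from ``class_map`` are treated as
    uninformative with a logged warning.
    """
    best_pos: Optional[Tuple[float, str]] = None
    best_neg: Optional[Tuple[float, str]] = None
    for domain_id, e_value in domain_hits:
        if e_value < 0:
            raise ValueError(f"negative E-value {e_value} for domain {domain_id}")
        cls = class_map.get(domain_id)
        if cls is None:
            logger.warning(
                "domain %r not in class map; treated as uninformative", domain_id
            )
            continue
        key = (e_value, domain_id)
        if cls == "positive" and (best_pos is None or key < best_pos):
            best_pos = key
        elif cls == "negative" and (best_neg is None or key < best_neg):
            best_neg = key
    missing = evalue_score(missing_evalue, score_cap)
    pos_score = evalue_score(best_pos[0], score_cap) if best_pos else missing
    neg_score = evalue_score(best_neg[0], score_cap) if best_neg else missing
    return Superiority(
        candidate_id=candidate_id,
        score=pos_score - neg_score,
        best_positive_domain=best_pos[1] if best_pos else None,
        best_negative_domain=best_neg[1] if best_neg else None,
    )


def decide(
    quality_score: Optional[float],
    superiority_score: float,
    thresholds: Thresholds,
    strict_inequality: bool = True,
) -> Decision:
    """Accept iff both scores exceed their thresholds.

    "Exceeds" is a strict ``>`` by default (configurable to ``>=``).  A
    ``None`` quality (a candidate injected after the sensitivity phase, so
    never a search subject) bypasses the quality test.  The reason code
    names the first failed test, quality before superiority.
    """

    def exceeds(score: float, cutoff: float) -> bool:
        return score > cutoff if strict_inequality else score >= cutoff

    if quality_score is not None and not exceeds(quality_score, thresholds.quality_min):
        return Decision(False, "quality")
    if not exceeds(superiority_score, thresholds.superiority_min):
        return Decision(False, "superiority")
    return Decision(True, "ok")
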