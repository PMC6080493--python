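"""Validation statistics: annotation-conditioned error rates, the
quality x superiority heat-map grid, and the quality~superiority regression.

Error rates are "conditioned on annotation accuracy": classifier decisions
are compared against each record's annotation call (target / non_target /
ambiguous), taking the annotations as ground truth.  Ambiguous calls sit in
the denominator only (a flag excludes them entirely).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Literal, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

AnnotationCall = Literal["target", "non_target", "ambiguous"]
VALID_CALLS = ("target", "non_target", "ambiguous")


@dataclass(frozen=True)
class RateResult:
    rate_percent: float
    n_target: int
    n_non_target: int
    n_ambiguous: int

    @property
    def total(self) -> int:
        return self.n_target + self.n_non_target + self.n_ambiguous

    def formatted(self, sig: int = 2) -> str:
        """The rate as a percentage string at ``sig`` significant figures."""
        if self.rate_percent == 0:
            return "0%"
        return f"{float(f'%.{sig}g' % self.rate_percent):g}%"


def _breakdown(
    ids: Iterable[str], annotations: Mapping[str, AnnotationCall]
) -> Tuple[int, int, int]:
    counts = {"target": 0, "non_target": 0, "ambiguous": 0}
    missing: List[str] = []
    for i in ids:
        call = annotations.get(i)
        if call is None:
            missing.append(i)
        elif call not in counts:
            raise ValueError(f"unknown annotation call {call!r} for id {i!r}")
        else:
            counts[call] += 1
    if missing:
        shown = ", ".join(missing[:10])
        raise ValueError(
            f"{len(missing)} ids lack annotation calls: {shown}"
            + ("..." if len(missing) > 10 else "")
        )
    return counts["target"], counts["non_target"], counts["ambiguous"]


def fp_rate(
    accepted_ids: Iterable[str],
    annotations: Mapping[str, AnnotationCall],
    include_ambiguous: bool = True,
) -> RateResult:
    """False-positive rate over the accepted set, as a percentage.

    rate = n_non_target / (n_target + n_non_target + n_ambiguous); with
    ``include_ambiguous=False`` ambiguous records leave the denominator.
    """
    n_t, n_nt, n_amb = _breakdown(accepted_ids, annotations)
    denom = n_t + n_nt + (n_amb if include_ambiguous else 0)
    rate = 100.0 * n_nt / denom if denom else 0.0
    return RateResult(rate, n_t, n_nt, n_amb)


def fn_rate(
    relaxed_only_ids: Iterable[str],
    annotations: Mapping[str, AnnotationCall],
    include_ambiguous: bool = True,
) -> RateResult:
    """False-negative rate over the relaxed-only set, as a percentage.

    ``relaxed_only_ids`` are the records accepted at the relaxed thresholds
    but rejected at the strict ones (hence classified non-target); those
    annotated as target are the false negatives.
    """
    n_t, n_nt, n_amb = _breakdown(relaxed_only_ids, annotations)
    denom = n_t + n_nt + (n_amb if include_ambiguous else 0)
    rate = 100.0 * n_t / denom if denom else 0.0
    return RateResult(rate, n_t, n_nt, n_amb)


@dataclass
class HeatGrid:
    """2-D histogram of (quality, superiority) points.

    Bins are half-open ``[edge, edge + width)``: a point on an edge falls
    in the higher bin.  ``counts[i, j]`` counts points in quality bin i and
    superiority bin j.
    """

    quality_edges: np.ndarray
    superiority_edges: np.ndarray
    counts: np.ndarray

    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path) -> None:
        header = "\t".join(
            f"s[{lo:g},{hi:g})"
            for lo, hi in zip(self.superiority_edges, self.superiority_edges[1:])
        )
        with open(path, "w") as fh:
            fh.write("quality_bin\t" + header + "\n")
            for i, lo in enumerate(self.quality_edges[:-1]):
                row = "\t".join(str(int(c)) for c in self.counts[i])
                fh.write(f"[{lo:g},{self.quality_edges[i + 1]:g})\t{row}\n")


def heat_grid(
    points: Sequence[Tuple[float, float]],
    bin_width_q: float,
    bin_width_s: float,
) -> HeatGrid:
    """Bin (quality, superiority) points on a regular half-open grid."""
    if bin_width_q <= 0 or bin_width_s <= 0:
        raise ValueError("bin widths must be positive")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (quality, superiority) pairs")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite scores cannot be binned")
    q, s = pts[:, 0], pts[:, 1]
    qi = np.floor(q / bin_width_q).astype(int)
    si = np.floor(s / bin_width_s).astype(int)
    q0, q1 = qi.min(), qi.max()
    s0, s1 = si.min(), si.max()
    counts = np.zeros((q1 - q0 + 1, s1 - s0 + 1), dtype=int)
    np.add.at(counts, (qi - q0, si - s0), 1)
    q_edges = np.arange(q0, q1 + 2) * bin_width_q
    s_edges = np.arange(s0, s1 + 2) * bin_width_s
    return HeatGrid(q_edges, s_edges, counts)


def regression_r2(
    points: Sequence[Tuple[float, float]]
) -> Tuple[float, float, float]:
    """OLS of superiority on quality: returns (slope, intercept, r_squared).

    The coefficient of determination quantifies how little of the
    superiority variation quality explains; a value near 0 shows the two
    statistics carry independent information.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a regression")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in quality; regression undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def read_annotation_calls(path) -> Dict[str, AnnotationCall]:
    """Read a two-column TSV of id <tab> call."""
    calls: Dict[str, AnnotationCall] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            call = fields[1].strip().lower()
            if call not in VALID_CALLS:
                raise ValueError(f"{path}:{lineno}: unknown call {fields[1]!r}")
            if fields[0] in calls:
                raise ValueError(f"{path}:{lineno}: duplicate id {fields[0]!r}")
            calls[fields[0]] = call  # type: ignore[assignment]
    return calls
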