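"""Orchestration: sensitivity phase -> candidate injection -> specificity
phase -> taxon/length filters, with full per-record provenance.

The miner proceeds in two search-driven phases.  The sensitivity phase
retains every subject of the homology search whose quality exceeds the
quality threshold.  Externally sourced candidates (e.g. protein equivalents
of a curated nucleotide collection) can then be injected into the pool;
they were never search subjects, so they bypass the quality test.  The
specificity phase computes each candidate's superiority from its
conserved-domain hits and makes the accept/reject decision.  Finally,
candidates shorter than 95 aa or outside the target taxon (Metazoa) are
rejected regardless of score.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from . import genbank_extract
from .genbank_extract import SeqRecordGB
from .hit_io import (
    DomainClassMap,
    DomainHitTable,
    HitTable,
    read_class_map,
    read_domain_hits,
    read_hit_table,
)
from .scoring import Thresholds, compute_quality, compute_superiority, decide

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN_AA = 95
DEFAULT_REQUIRED_TAXON = "Metazoa"


@dataclass
class Candidate:
    """One candidate sequence with its scores, provenance and decision."""

    id: str
    quality: Optional[float] = None
    superiority: Optional[float] = None
    length_aa: int = 0
    lineage: List[str] = field(default_factory=list)
    injected: bool = False
    decision: Optional[str] = None  # "accepted" | "rejected"
    reason: Optional[str] = None

    @property
    def accepted(self) -> bool:
        return self.decision == "accepted"


@dataclass
class RunReport:
    """Bookkeeping for one classification run."""

    thresholds: Thresholds
    reason_counts: Dict[str, int] = field(default_factory=dict)
    n_candidates: int = 0
    n_accepted: int = 0
    n_injected: int = 0
    n_injection_skipped: int = 0
    n_missing_lineage: int = 0
    input_manifest: Dict[str, str] = field(default_factory=dict)
    config_hash: str = ""

    def reconcile(self, pool: Mapping[str, Candidate]) -> None:
        self.n_candidates = len(pool)
        self.n_accepted = sum(1 for c in pool.values() if c.accepted)
        counts: Dict[str, int] = {}
        for c in pool.values():
            counts[c.reason or "undecided"] = counts.get(c.reason or "undecided", 0) + 1
        self.reason_counts = counts
        assert sum(counts.values()) == self.n_candidates

    def to_dict(self) -> Dict:
        return {
            "thresholds": {
                "quality_min": self.thresholds.quality_min,
                "superiority_min": self.thresholds.superiority_min,
                "label": self.thresholds.label,
            },
            "n_candidates": self.n_candidates,
            "n_accepted": self.n_accepted,
            "n_injected": self.n_injected,
            "n_injection_skipped": self.n_injection_skipped,
            "n_missing_lineage": self.n_missing_lineage,
            "reason_counts": self.reason_counts,
            "input_manifest": self.input_manifest,
            "config_hash": self.config_hash,
        }


def sensitivity_phase(
    hits: HitTable, thresholds: Thresholds
) -> Dict[str, Candidate]:
    """Score every distinct subject once and retain those whose quality
    exceeds the quality threshold."""
    pool: Dict[str, Candidate] = {}
    if not hits.rows:
        logger.warning("empty hit table: sensitivity phase retains nothing")
        return pool
    for subject in hits.subjects():
        q = compute_quality(hits.rows, subject)
        if decide(q.score, float("inf"), thresholds).reason != "quality":
            pool[subject] = Candidate(id=subject, quality=q.score)
    return pool


def inject_candidates(
    pool: Dict[str, Candidate],
    extra_ids: Iterable[str],
    registry: Mapping[str, SeqRecordGB],
) -> int:
    """Add externally sourced candidates to the pool.

    Ids already in the pool keep their quality (a provenance note only);
    unresolvable ids are logged and skipped.  Returns the skip count.
    """
    skipped = 0
    for cid in extra_ids:
        if cid in pool:
            pool[cid].injected = True
            continue
        if cid not in registry:
            logger.warning("injection id %r not resolvable; skipped", cid)
            skipped += 1
            continue
        pool[cid] = Candidate(id=cid, quality=None, injected=True)
    return skipped


def specificity_phase(
    pool: Dict[str, Candidate],
    domain_hits: DomainHitTable,
    class_map: DomainClassMap,
    thresholds: Thresholds,
) -> None:
    """Compute superiority for every pooled candidate and decide.

    Candidates with no domain hits fall back to the missing-class
    convention (superiority 0).  Filter rejections recorded earlier are
    left untouched.
    """
    by_candidate: Dict[str, List] = {}
    for cid, domain, e_value in domain_hits.rows:
        by_candidate.setdefault(cid, []).append((domain, e_value))
    for cid, cand in pool.items():
        sup = compute_superiority(
            by_candidate.get(cid, []), class_map, candidate_id=cid
        )
        cand.superiority = sup.score
        if cand.reason in ("short", "non-target-taxon"):
            continue
        d = decide(cand.quality, sup.score, thresholds)
        cand.decision = "accepted" if d.accepted else "rejected"
        cand.reason = d.reason if not d.accepted else "ok"


def apply_filters(
    pool: Dict[str, Candidate],
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
    required_taxon: str = DEFAULT_REQUIRED_TAXON,
) -> int:
    """Reject candidates shorter than ``min_len_aa`` or whose lineage lacks
    ``required_taxon`` (exact, case-sensitive taxon-name match).

    Filter rejections take precedence over score-based decisions, so the
    accepted set is the same whether filters run before or after the
    specificity phase.  A missing lineage counts as non-target-taxon and is
    additionally tallied separately (the returned count).
    """
    missing_lineage = 0
    for cand in pool.values():
        if cand.length_aa < min_len_aa:
            cand.decision, cand.reason = "rejected", "short"
        elif required_taxon not in cand.lineage:
            if not cand.lineage:
                missing_lineage += 1
            cand.decision, cand.reason = "rejected", "non-target-taxon"
    return missing_lineage


def populate_metadata(
    pool: Dict[str, Candidate], registry: Mapping[str, SeqRecordGB]
) -> None:
    """Fill lengths and lineages from the sequence registry."""
    for cid, cand in pool.items():
        rec = registry.get(cid)
        if rec is not None:
            cand.length_aa = rec.length
            cand.lineage = list(rec.lineage)


@dataclass
class RunConfig:
    """File-level inputs for one classification run."""

    corpus_genbank: Path
    hit_table: Path
    domain_hits: Path
    class_map: Path
    out_dir: Path
    injection_list: Optional[Path] = None
    thresholds: Thresholds = field(default_factory=Thresholds.strict)
    min_len_aa: int = DEFAULT_MIN_LEN_AA
    required_taxon: str = DEFAULT_REQUIRED_TAXON
    filters_first: bool = False

    def manifest(self) -> Dict[str, str]:
        out = {
            "corpus_genbank": str(self.corpus_genbank),
            "hit_table": str(self.hit_table),
            "domain_hits": str(self.domain_hits),
            "class_map": str(self.class_map),
        }
        if self.injection_list:
            out["injection_list"] = str(self.injection_list)
        return out

    def digest(self) -> str:
        payload = json.dumps(
            {
                **self.manifest(),
                "thresholds": [
                    self.thresholds.quality_min,
                    self.thresholds.superiority_min,
                ],
                "min_len_aa": self.min_len_aa,
                "required_taxon": self.required_taxon,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run(config: RunConfig) -> tuple[Dict[str, Candidate], RunReport]:
    """Execute a full classification run and write the output trio.

    Every corpus record ends with exactly one decision: subjects below the
    quality threshold (or never hit at all) are rejected "quality";
    pooled candidates are decided by the specificity phase and the
    length/taxon filters.  Deterministic given the inputs.
    """
    for name, path in config.manifest().items():
        if not Path(path).exists():
            raise FileNotFoundError(f"{name} input missing: {path}")

    records = genbank_extract.parse_flatfile(Path(config.corpus_genbank))
    registry = {r.accession: r for r in records if r.sequence and not _is_nuc(r)}
    nuc_store = {r.accession: r.sequence for r in records if _is_nuc(r)}

    hits = read_hit_table(config.hit_table)
    domain_table = read_domain_hits(config.domain_hits)
    class_map = read_class_map(config.class_map)

    pool = sensitivity_phase(hits, config.thresholds)
    n_skipped = 0
    if config.injection_list:
        extra = [
            line.strip()
            for line in Path(config.injection_list).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        n_skipped = inject_candidates(pool, extra, registry)
    populate_metadata(pool, registry)

    if config.filters_first:
        n_missing = apply_filters(pool, config.min_len_aa, config.required_taxon)
        specificity_phase(pool, domain_table, class_map, config.thresholds)
    else:
        specificity_phase(pool, domain_table, class_map, config.thresholds)
        n_missing = apply_filters(pool, config.min_len_aa, config.required_taxon)

    # Corpus protein records that never entered the pool failed sensitivity.
    for acc, rec in registry.items():
        if acc not in pool:
            pool[acc] = Candidate(
                id=acc,
                length_aa=rec.length,
                lineage=list(rec.lineage),
                decision="rejected",
                reason="quality",
            )

    report = RunReport(thresholds=config.thresholds)
    report.n_injected = sum(1 for c in pool.values() if c.injected)
    report.n_injection_skipped = n_skipped
    report.n_missing_lineage = n_missing
    report.input_manifest = config.manifest()
    report.config_hash = config.digest()
    report.reconcile(pool)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    accepted = sorted(
        (c for c in pool.values() if c.accepted), key=lambda c: c.id
    )
    accepted_records = [registry[c.id] for c in accepted if c.id in registry]
    genbank_extract.write_outputs(
        accepted_records,
        nuc_store,
        out_dir / "accepted_proteins.fasta",
        out_dir / "accepted_nucleotides.fasta",
        out_dir / "accepted_accessions.csv",
    )
    with (out_dir / "run_report.json").open("w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return pool, report


def _is_nuc(rec: SeqRecordGB) -> bool:
    if rec.molecule_type:
        return "protein" not in rec.molecule_type.lower()
    letters = set(rec.sequence.upper())
    return bool(letters) and letters <= set("ACGTUN")
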