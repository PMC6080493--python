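"""Readers and writers for tabular hit files and the domain class map.

The engine is decoupled from live search tools: it consumes BLAST
outfmt-6-style tab-separated hit tables (12 columns; query, subject, %id,
length, mismatches, gapopen, qstart, qend, sstart, send, evalue, bitscore)
for both the protein homology search and the conserved-domain search, plus
a two-column TSV mapping each conserved-domain id to a class in
{positive, negative, uninformative}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple, Union

from .scoring import DomainClass

logger = logging.getLogger(__name__)

N_COLUMNS = 12
VALID_CLASSES = ("positive", "negative", "uninformative")


class HitTableFormatError(ValueError):
    """A malformed line in a tabular hit file; message names the line."""


@dataclass
class HitTable:
    """Homology-search hits: (query_id, subject_id, e_value) rows."""

    rows: List[Tuple[str, str, float]] = field(default_factory=list)
    source_label: str = ""

    def subjects(self) -> List[str]:
        """Distinct subject ids in first-seen order."""
        seen: Dict[str, None] = {}
        for _, subject, _ in self.rows:
            seen.setdefault(subject)
        return list(seen)


@dataclass
class DomainHitTable:
    """Conserved-domain hits: (candidate_id, domain_id, e_value) rows."""

    rows: List[Tuple[str, str, float]] = field(default_factory=list)

    def hits_for(self, candidate_id: str) -> List[Tuple[str, float]]:
        return [(d, e) for c, d, e in self.rows if c == candidate_id]


@dataclass
class DomainClassMap:
    """Curated domain_id -> positive/negative/uninformative labeling."""

    entries: Dict[str, DomainClass] = field(default_factory=dict)

    def __getitem__(self, domain_id: str) -> DomainClass:
        return self.entries[domain_id]

    def get(self, domain_id: str, default=None):
        return self.entries.get(domain_id, default)


def _parse_tabular(path: Union[str, Path]) -> List[Tuple[int, List[str]]]:
    path = Path(path)
    out: List[Tuple[int, List[str]]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != N_COLUMNS:
                raise HitTableFormatError(
                    f"{path.name}:{lineno}: expected {N_COLUMNS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            out.append((lineno, fields))
    if not out:
        logger.warning("%s: no hit rows (empty table)", path)
    return out


def _parse_evalue(text: str, path: Path, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise HitTableFormatError(
            f"{path.name}:{lineno}: unparseable E-value {text!r}"
        ) from None
    if value < 0:
        raise HitTableFormatError(
            f"{path.name}:{lineno}: negative E-value {text!r}"
        )
    return value


def read_hit_table(path: Union[str, Path], source_label: str = "") -> HitTable:
    """Read a 12-column homology-search hit table (columns 1, 2, 11 used).

    ``#`` comment lines and blank lines are skipped; any other malformed
    line raises :class:`HitTableFormatError` naming the line number.
    """
    path = Path(path)
    rows = []
    for lineno, fields in _parse_tabular(path):
        e_value = _parse_evalue(fields[10], path, lineno)
        query, subject = fields[0], fields[1]
        if not query or not subject:
            raise HitTableFormatError(
                f"{path.name}:{lineno}: empty query or subject id"
            )
        rows.append((query, subject, e_value))
    return HitTable(rows=rows, source_label=source_label or path.name)


def read_domain_hits(path: Union[str, Path]) -> DomainHitTable:
    """Read conserved-domain hits; a ``CDD:`` prefix on the subject id is
    stripped to normalize domain ids.  Duplicate (candidate, domain) rows
    are kept (the minimum E-value is taken downstream)."""
    path = Path(path)
    rows = []
    for lineno, fields in _parse_tabular(path):
        e_value = _parse_evalue(fields[10], path, lineno)
        candidate, domain = fields[0], fields[1]
        if not candidate or not domain:
            raise HitTableFormatError(
                f"{path.name}:{lineno}: empty candidate or domain id"
            )
        if domain.startswith("CDD:"):
            domain = domain[len("CDD:"):]
        rows.append((candidate, domain, e_value))
    return DomainHitTable(rows=rows)


def read_class_map(path: Union[str, Path]) -> DomainClassMap:
    """Read the two-column domain_id <tab> class table.

    Class strings are validated case-insensitively against
    {positive, negative, uninformative}; a domain listed twice with
    conflicting classes is an error.
    """
    path = Path(path)
    entries: Dict[str, DomainClass] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise HitTableFormatError(
                    f"{path.name}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            domain, cls = fields[0].strip(), fields[1].strip().lower()
            if cls not in VALID_CLASSES:
                raise HitTableFormatError(
                    f"{path.name}:{lineno}: unknown class {fields[1]!r} "
                    f"(expected one of {', '.join(VALID_CLASSES)})"
                )
            if domain in entries and entries[domain] != cls:
                raise HitTableFormatError(
                    f"{path.name}:{lineno}: domain {domain!r} reclassified "
                    f"{entries[domain]!r} -> {cls!r}"
                )
            entries[domain] = cls  # type: ignore[assignment]
    return DomainClassMap(entries=entries)


def _format_row(query: str, subject: str, e_value: float) -> str:
    # Only columns 1, 2 and 11 are meaningful to the engine; the rest are
    # placeholders keeping the 12-column dialect intact.
    return "\t".join(
        [query, subject, "0.0", "0", "0", "0", "0", "0", "0", "0",
         format(e_value, ".3g"), "0.0"]
    )


def write_hit_table(table: HitTable, path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        for query, subject, e_value in table.rows:
            fh.write(_format_row(query, subject, e_value) + "\n")


def write_domain_hits(table: DomainHitTable, path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        for candidate, domain, e_value in table.rows:
            fh.write(_format_row(candidate, domain, e_value) + "\n")


def write_class_map(cmap: DomainClassMap, path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        for domain, cls in cmap.entries.items():
            fh.write(f"{domain}\t{cls}\n")
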