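"""GenBank flat-file parsing, coded_by CDS extraction, and output writers.

Accepted protein records are linked back to their nucleotide records via
the CDS feature's ``/coded_by`` qualifier, whose value locates the coding
sequence on a nucleotide accession in GenBank's 1-based inclusive
coordinates with optional ``complement(...)`` / ``join(...)`` nesting and
``<`` / ``>`` partial-end markers.  Internally all coordinates are 0-based
half-open; conversion happens only at the parse/format boundary.

Outputs follow the published formats: single-line FASTA with deflines of
``accession__binomial__taxonomy`` (fields delimited by double underscores,
binomial and taxonomy internally delimited by semicolons) and a CSV of
``protein_accession,nucleotide_accession`` pairs with ``n/a`` when the
nucleotide record is unavailable.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import Location as _BioLocation

logger = logging.getLogger(__name__)


class UnsupportedLocationError(ValueError):
    """A coded_by construct outside the supported grammar subset."""


@dataclass
class Location:
    """A parsed coded_by location in 0-based half-open coordinates."""

    ref_accession: Optional[str]
    segments: List[Tuple[int, int]]
    strand: str = "+"
    partial_5p: bool = False
    partial_3p: bool = False

    def __post_init__(self) -> None:
        for start, end in self.segments:
            if start >= end:
                raise ValueError(f"empty or inverted segment ({start}, {end})")
        starts = [s for s, _ in self.segments]
        if starts != sorted(starts):
            raise ValueError("segments must ascend on the reference")
        for (_, e1), (s2, _) in zip(self.segments, self.segments[1:]):
            if s2 < e1:
                raise ValueError("segments overlap")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class SeqRecordGB:
    """The fields of a GenBank flat-file record the miner consumes."""

    accession: str
    sequence: str
    product: Optional[str] = None
    lineage: List[str] = field(default_factory=list)
    binomial: Optional[str] = None
    coded_by: Optional[str] = None
    dbsource: Optional[str] = None
    source_feature: Optional[str] = None
    molecule_type: Optional[str] = None  # e.g. "protein", "DNA"

    @property
    def length(self) -> int:
        return len(self.sequence)


def parse_location(s: str) -> Location:
    """Parse a coded_by-style location string.

    Supported grammar subset: ``a..b``, ``acc.ver:a..b``,
    ``complement(X)``, ``join(X,Y,...)``, partial markers ``<a`` / ``>b``,
    and ``complement(join(...))`` nesting.  Anything else (``order(...)``,
    ``a^b`` sites, ...) raises :class:`UnsupportedLocationError`.
    """
    text = s.strip()
    for construct in ("order(", "bond(", "one-of("):
        if construct in text:
            raise UnsupportedLocationError(
                f"unsupported location construct {construct[:-1]!r} in {s!r}"
            )
    if "^" in text:
        raise UnsupportedLocationError(
            f"unsupported location construct '^' (site) in {s!r}"
        )
    try:
        bio_loc = _BioLocation.fromstring(text)
    except Exception as exc:
        raise UnsupportedLocationError(f"cannot parse location {s!r}: {exc}") from None
    if bio_loc is None:
        raise UnsupportedLocationError(f"cannot parse location {s!r}")

    refs = {p.ref for p in bio_loc.parts} - {None}
    if len(refs) > 1:
        raise UnsupportedLocationError(f"multiple reference accessions in {s!r}")
    refs = refs or {None}
    strand = "-" if bio_loc.strand == -1 else "+"
    segments = sorted((int(p.start), int(p.end)) for p in bio_loc.parts)
    return Location(
        ref_accession=next(iter(refs)),
        segments=segments,
        strand=strand,
        partial_5p="<" in text,
        partial_3p=">" in text,
    )


def format_location(loc: Location) -> str:
    """Render a Location back to the GenBank 1-based inclusive grammar."""
    parts = []
    for i, (start, end) in enumerate(loc.segments):
        a = f"{start + 1}"
        b = f"{end}"
        if loc.partial_5p and i == 0:
            a = "<" + a
        if loc.partial_3p and i == len(loc.segments) - 1:
            b = ">" + b
        parts.append(f"{a}..{b}")
    body = parts[0] if len(parts) == 1 else "join(" + ",".join(parts) + ")"
    if loc.ref_accession:
        if len(parts) > 1:
            raise ValueError("cannot render a multi-segment location with a "
                             "reference accession prefix")
        body = f"{loc.ref_accession}:{body}"
    if loc.strand == "-":
        body = f"complement({body})"
    return body


def _feature_to_text(feature) -> str:
    """Flatten a Biopython feature's qualifiers to a searchable string."""
    chunks = []
    for key, values in feature.qualifiers.items():
        for value in values:
            chunks.append(f'/{key}="{value}"')
    return " ".join(chunks)


def parse_flatfile(source: Union[str, Path, io.TextIOBase]) -> List[SeqRecordGB]:
    """Parse GenBank flat-file text (one or more LOCUS..// records).

    Extracts accession, sequence, DBSOURCE, organism binomial + lineage,
    the CDS ``/coded_by`` qualifier, the source feature (for BOLD
    db_xref detection), and the CDS or Protein ``/product``.  Records
    lacking an accession or a sequence are skipped with a warning.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        handle: io.TextIOBase = open(source)
        close = True
    elif isinstance(source, str):
        handle = io.StringIO(source)
        close = False
    else:
        handle = source  # type: ignore[assignment]
        close = False
    out: List[SeqRecordGB] = []
    try:
        for rec in SeqIO.parse(handle, "genbank"):
            accession = rec.annotations.get("accessions", [rec.id or ""])
            accession = accession[0] if accession else ""
            sequence = str(rec.seq).upper() if rec.seq is not None else ""
            if not accession or not sequence:
                logger.warning(
                    "skipping record %r: missing accession or sequence", rec.id
                )
                continue
            coded_by = None
            product = None
            source_feature = None
            for feat in rec.features:
                if feat.type == "CDS":
                    coded_by = feat.qualifiers.get("coded_by", [None])[0]
                    product = product or feat.qualifiers.get("product", [None])[0]
                elif feat.type == "Protein":
                    product = product or feat.qualifiers.get("product", [None])[0]
                elif feat.type == "source":
                    source_feature = _feature_to_text(feat)
            organism = rec.annotations.get("organism") or None
            out.append(
                SeqRecordGB(
                    accession=accession,
                    sequence=sequence,
                    product=product,
                    lineage=list(rec.annotations.get("taxonomy", [])),
                    binomial=organism,
                    coded_by=coded_by,
                    dbsource=rec.annotations.get("db_source"),
                    source_feature=source_feature,
                    molecule_type=rec.annotations.get("molecule_type"),
                )
            )
    finally:
        if close:
            handle.close()
    return out


class NucleotideUnavailableError(KeyError):
    """The nucleotide record named by a coded_by location is not on hand."""


def extract_cds(loc: Location, nuc_store: Mapping[str, str]) -> str:
    """Extract the coding sequence a Location points at.

    Segments are concatenated in ascending reference order; on the minus
    strand the concatenation is reverse-complemented (IUPAC-aware).
    """
    ref = loc.ref_accession
    if ref is None and len(nuc_store) == 1:
        # A bare "a..b" location is unambiguous against a single sequence.
        ref = next(iter(nuc_store))
    if ref is not None and ref not in nuc_store and "." in ref:
        # a versioned accession may be stored unversioned
        base = ref.rsplit(".", 1)[0]
        if base in nuc_store:
            ref = base
    if ref is None or ref not in nuc_store:
        raise NucleotideUnavailableError(
            f"nucleotide record unavailable: {loc.ref_accession!r}"
        )
    nuc = nuc_store[ref]
    for start, end in loc.segments:
        if end > len(nuc):
            raise ValueError(
                f"segment ({start}, {end}) out of bounds for "
                f"{loc.ref_accession} (length {len(nuc)})"
            )
    cds = "".join(nuc[start:end] for start, end in loc.segments)
    if loc.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


_BOLD_XREF = re.compile(r'/db_xref="BOLD:([^"]*)"')


def detect_bold(rec: SeqRecordGB) -> bool:
    """True iff the record carries a BOLD db_xref whose value contains COI."""
    for text in (rec.source_feature, rec.dbsource):
        if not text:
            continue
        for match in _BOLD_XREF.finditer(text):
            if "COI" in match.group(1):
                return True
    return False


def make_defline(
    accession: str, binomial: Optional[str], lineage: Sequence[str]
) -> str:
    """``accession__binomial__taxonomy``, binomial and taxonomy internally
    semicolon-delimited; a missing binomial renders as an empty field."""
    binomial_part = ";".join(binomial.split()) if binomial else ""
    return f"{accession}__{binomial_part}__{';'.join(lineage)}"


def write_outputs(
    records: Sequence[SeqRecordGB],
    nuc_store: Mapping[str, str],
    protein_fasta: Union[str, Path],
    nucleotide_fasta: Union[str, Path],
    accession_csv: Union[str, Path],
) -> Dict[str, int]:
    """Write the published output trio for a set of accepted records.

    Protein FASTA (every record), nucleotide FASTA (records whose coded_by
    resolves in ``nuc_store``), and the accession-pair CSV with ``n/a``
    for unavailable nucleotides.  Sequences are single-line so that
    ``grep -A 1`` retrieves a full record.
    """
    n_nuc = 0
    with open(protein_fasta, "w") as pf, open(nucleotide_fasta, "w") as nf, \
            open(accession_csv, "w") as cf:
        for rec in records:
            defline = make_defline(rec.accession, rec.binomial, rec.lineage)
            pf.write(f">{defline}\n{rec.sequence}\n")
            nuc_acc = "n/a"
            if rec.coded_by:
                try:
                    loc = parse_location(rec.coded_by)
                    cds = extract_cds(loc, nuc_store)
                except (UnsupportedLocationError, NucleotideUnavailableError):
                    pass
                else:
                    nuc_acc = loc.ref_accession or "n/a"
                    nuc_defline = make_defline(nuc_acc, rec.binomial, rec.lineage)
                    nf.write(f">{nuc_defline}\n{cds}\n")
                    n_nuc += 1
            cf.write(f"{rec.accession},{nuc_acc}\n")
    return {"proteins": len(records), "nucleotides": n_nuc}
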