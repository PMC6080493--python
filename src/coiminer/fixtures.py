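"""Synthetic input universe with recorded ground truth.

Generates everything the miner consumes — protein and nucleotide GenBank
flat files, a homology-search hit table, a conserved-domain hit table, the
domain class map and a truth table — so that every module is testable
offline.  E-values are drawn directly from per-category log-uniform ranges
rather than produced by running a search tool, which keeps the suite
hermetic; the ranges are placed well clear of the strict (0.9, 5)
thresholds so the intended decision of every record is known by
construction.

Record categories:

* ``target`` — true COI: high quality, strongly positive superiority,
  metazoan lineage, length >= 95 aa.  Expected accepted.
* ``paralog`` — off-target mitochondrial gene (ND1/COX2/CYTB analog):
  passes the sensitivity phase but its best domain match is negative-class,
  so superiority is strongly negative.  Expected rejected (superiority).
* ``decoy`` — unrelated protein: hit weakly or not at all.  Expected
  rejected (quality).
* ``short`` — target-like scores but < 95 aa.  Expected rejected (short).
* ``non_metazoan`` — target-like scores, non-metazoan lineage.  Expected
  rejected (non-target-taxon).

Every protein record's GenBank entry carries a ``coded_by`` location
(cycling through plain, complement, join and complement(join) forms) whose
extracted CDS translates to the protein under the invertebrate
mitochondrial code (NCBI table 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable

from .threshold_tuner import TrainingPoint

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

POSITIVE_DOMAINS = ("COX1_repeat", "Cyt_c_Oxidase_I")
NEGATIVE_DOMAINS = ("ND1", "ND2", "COX2", "CYTB", "Laglidadg")
UNINFORMATIVE_DOMAINS = ("Transmembrane_generic",)

METAZOAN_LINEAGES = (
    ["Eukaryota", "Metazoa", "Arthropoda", "Insecta"],
    ["Eukaryota", "Metazoa", "Chordata", "Actinopterygii"],
    ["Eukaryota", "Metazoa", "Mollusca", "Gastropoda"],
    ["Eukaryota", "Metazoa", "Annelida", "Polychaeta"],
    ["Eukaryota", "Metazoa", "Cnidaria", "Anthozoa"],
)
NON_METAZOAN_LINEAGES = (
    ["Eukaryota", "Viridiplantae", "Streptophyta"],
    ["Eukaryota", "Fungi", "Ascomycota"],
    ["Bacteria", "Proteobacteria"],
)

REPRESENTATIVE_QUERIES = tuple(f"REP{i:02d}" for i in range(1, 11))

GENERA = (
    "Drosophila", "Apis", "Danio", "Mytilus", "Lumbricus",
    "Nematostella", "Daphnia", "Salmo", "Helix", "Nereis",
)
EPITHETS = ("melanogaster", "mellifera", "rerio", "edulis", "terrestris",
            "vectensis", "pulex", "salar", "pomatia", "virens")


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic corpus; the defaults are the study conditions."""

    n_target: int = 200
    n_paralog: int = 50
    n_decoy: int = 30
    n_short: int = 20
    n_nontaxon: int = 20
    seed: int = 0
    #: log10 E-value range of sensitivity-phase hits for records meant to
    #: pass the quality threshold
    hit_loge_range: Tuple[float, float] = (-50.0, -20.0)
    #: log10 E-value range of the best same-class domain match
    strong_domain_loge_range: Tuple[float, float] = (-80.0, -40.0)
    #: log10 E-value range of weak cross-class domain matches
    weak_domain_loge_range: Tuple[float, float] = (-4.0, 0.0)
    length_range_aa: Tuple[int, int] = (95, 220)
    short_length_range_aa: Tuple[int, int] = (40, 94)
    genetic_code: int = 5
    include_worked_example: bool = False

    def __post_init__(self) -> None:
        for name in ("n_target", "n_paralog", "n_decoy", "n_short", "n_nontaxon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("length_range_aa", "short_length_range_aa"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if self.short_length_range_aa[1] >= 95:
            raise ValueError("short records must stay below 95 aa")
        if self.length_range_aa[0] < 95:
            raise ValueError("regular records must be at least 95 aa")


@dataclass
class FixtureRecord:
    accession: str
    category: str
    protein: str
    lineage: List[str]
    binomial: str
    nuc_accession: str
    coded_by: str
    nucleotide: str
    bold_xref: Optional[str]
    hit_rows: List[Tuple[str, str, float]]
    domain_rows: List[Tuple[str, str, float]]
    expected_decision: str
    expected_reason: str


@dataclass
class FixtureCorpus:
    spec: FixtureSpec
    records: List[FixtureRecord]

    def truth(self) -> Dict[str, Tuple[str, str]]:
        return {
            r.accession: (r.expected_decision, r.expected_reason)
            for r in self.records
        }


def _codon_map(table_id: int) -> Dict[str, List[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    out: Dict[str, List[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


def _back_translate(protein: str, codons: Dict[str, List[str]],
                    stop: str, rng: np.random.Generator) -> str:
    picks = [codons[aa][int(rng.integers(len(codons[aa])))] for aa in protein]
    return "".join(picks) + stop


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))


def _loguniform_evalue(rng: np.random.Generator,
                       loge_range: Tuple[float, float]) -> float:
    return float(10.0 ** rng.uniform(*loge_range))


def generate_corpus(spec: FixtureSpec) -> FixtureCorpus:
    """Build the in-memory corpus; ``write_corpus`` serializes it."""
    rng = np.random.default_rng(spec.seed)
    codons = _codon_map(spec.genetic_code)
    stop_codon = CodonTable.unambiguous_dna_by_id[spec.genetic_code].stop_codons[0]
    records: List[FixtureRecord] = []
    counter = 0

    categories = (
        [("target", spec.n_target)] + [("paralog", spec.n_paralog)]
        + [("decoy", spec.n_decoy)] + [("short", spec.n_short)]
        + [("non_metazoan", spec.n_nontaxon)]
    )
    for category, n in categories:
        for _ in range(n):
            counter += 1
            acc = f"SYN{counter:05d}"
            nuc_acc = f"NSYN{counter:05d}"
            if category == "short":
                length = int(rng.integers(*spec.short_length_range_aa)) \
                    if spec.short_length_range_aa[0] < spec.short_length_range_aa[1] \
                    else spec.short_length_range_aa[0]
            else:
                length = int(rng.integers(spec.length_range_aa[0],
                                          spec.length_range_aa[1] + 1))
            protein = _random_protein(length, rng)
            cds = _back_translate(protein, codons, stop_codon, rng)

            if category == "non_metazoan":
                lineage = list(NON_METAZOAN_LINEAGES[counter % len(NON_METAZOAN_LINEAGES)])
            else:
                lineage = list(METAZOAN_LINEAGES[counter % len(METAZOAN_LINEAGES)])
            binomial = (f"{GENERA[counter % len(GENERA)]} "
                        f"{EPITHETS[(counter // 3) % len(EPITHETS)]}")

            hit_rows: List[Tuple[str, str, float]] = []
            domain_rows: List[Tuple[str, str, float]] = []
            if category == "decoy":
                # half get a near-1 E-value hit (quality < 0.9), half none
                if counter % 2 == 0:
                    e = float(10.0 ** rng.uniform(-0.5, 0.0))
                    rep = REPRESENTATIVE_QUERIES[int(rng.integers(10))]
                    hit_rows.append((rep, acc, e))
                expected = ("rejected", "quality")
            else:
                n_hits = int(rng.integers(1, 4))
                reps = rng.choice(len(REPRESENTATIVE_QUERIES), size=n_hits,
                                  replace=False)
                for rep_i in reps:
                    e = _loguniform_evalue(rng, spec.hit_loge_range)
                    hit_rows.append((REPRESENTATIVE_QUERIES[rep_i], acc, e))
                if category == "paralog":
                    dom = NEGATIVE_DOMAINS[int(rng.integers(len(NEGATIVE_DOMAINS)))]
                    domain_rows.append(
                        (acc, dom, _loguniform_evalue(rng, spec.strong_domain_loge_range)))
                    if rng.random() < 0.5:
                        domain_rows.append(
                            (acc, POSITIVE_DOMAINS[0],
                             _loguniform_evalue(rng, spec.weak_domain_loge_range)))
                    expected = ("rejected", "superiority")
                else:  # target, short, non_metazoan: target-like scores
                    dom = POSITIVE_DOMAINS[int(rng.integers(len(POSITIVE_DOMAINS)))]
                    domain_rows.append(
                        (acc, dom, _loguniform_evalue(rng, spec.strong_domain_loge_range)))
                    if rng.random() < 0.5:
                        domain_rows.append(
                            (acc, NEGATIVE_DOMAINS[int(rng.integers(len(NEGATIVE_DOMAINS)))],
                             _loguniform_evalue(rng, spec.weak_domain_loge_range)))
                    if rng.random() < 0.3:
                        domain_rows.append(
                            (acc, UNINFORMATIVE_DOMAINS[0],
                             _loguniform_evalue(rng, spec.weak_domain_loge_range)))
                    expected = {
                        "target": ("accepted", "ok"),
                        "short": ("rejected", "short"),
                        "non_metazoan": ("rejected", "non-target-taxon"),
                    }[category]

            coded_by, nucleotide = _place_cds(cds, nuc_acc, counter, rng)
            bold = None
            if category == "target" and counter % 5 == 0:
                bold = f"BOLD:SYN{counter:05d}.COI-5P"
            records.append(FixtureRecord(
                accession=acc, category=category, protein=protein,
                lineage=lineage, binomial=binomial, nuc_accession=nuc_acc,
                coded_by=coded_by, nucleotide=nucleotide, bold_xref=bold,
                hit_rows=hit_rows, domain_rows=domain_rows,
                expected_decision=expected[0], expected_reason=expected[1],
            ))

    if spec.include_worked_example:
        records.append(_worked_example_record(codons, stop_codon, rng))
    return FixtureCorpus(spec=spec, records=records)


def _place_cds(cds: str, nuc_acc: str, counter: int,
               rng: np.random.Generator) -> Tuple[str, str]:
    """Embed the CDS in a nucleotide sequence under one of four coded_by
    location styles, cycling deterministically."""
    style = counter % 4
    flank5 = "".join("ACGT"[i] for i in rng.integers(4, size=int(rng.integers(5, 30))))
    flank3 = "".join("ACGT"[i] for i in rng.integers(4, size=int(rng.integers(5, 30))))
    if style == 0:  # plain forward
        nuc = flank5 + cds + flank3
        a, b = len(flank5) + 1, len(flank5) + len(cds)
        return f"{nuc_acc}.1:{a}..{b}", nuc
    if style == 1:  # complement
        rc = _revcomp(cds)
        nuc = flank5 + rc + flank3
        a, b = len(flank5) + 1, len(flank5) + len(rc)
        return f"complement({nuc_acc}.1:{a}..{b})", nuc
    # split the CDS at a codon-ish boundary for join styles
    cut = (len(cds) // 2) // 3 * 3 or 3
    left, right = cds[:cut], cds[cut:]
    gap = "".join("ACGT"[i] for i in rng.integers(4, size=int(rng.integers(5, 20))))
    if style == 2:  # join
        nuc = flank5 + left + gap + right + flank3
        a1, b1 = len(flank5) + 1, len(flank5) + len(left)
        a2 = b1 + len(gap) + 1
        b2 = a2 + len(right) - 1
        return f"join({nuc_acc}.1:{a1}..{b1},{a2}..{b2})", nuc
    # style 3: complement(join(...)) — the nucleotide holds the revcomp of
    # the full CDS; ascending segments concatenate to revcomp(cds)
    rc = _revcomp(cds)
    cut_rc = (len(rc) // 3) // 3 * 3 or 3
    left_rc, right_rc = rc[:cut_rc], rc[cut_rc:]
    nuc = flank5 + left_rc + gap + right_rc + flank3
    a1, b1 = len(flank5) + 1, len(flank5) + len(left_rc)
    a2 = b1 + len(gap) + 1
    b2 = a2 + len(right_rc) - 1
    return f"complement(join({nuc_acc}.1:{a1}..{b1},{a2}..{b2}))", nuc


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _worked_example_record(codons, stop_codon, rng) -> FixtureRecord:
    """A candidate carrying the canonical worked scores: quality 50
    (hits at E=1.0e-50 and 1.0e-40) and superiority 5 (positive domain at
    1.0e-70 vs negative at 1.0e-65) — rejected at strict thresholds,
    accepted at relaxed."""
    protein = _random_protein(150, rng)
    cds = _back_translate(protein, codons, stop_codon, rng)
    coded_by, nucleotide = _place_cds(cds, "NWEX00001", 0, rng)
    return FixtureRecord(
        accession="WEX00001", category="worked_example", protein=protein,
        lineage=list(METAZOAN_LINEAGES[0]), binomial="Apis mellifera",
        nuc_accession="NWEX00001", coded_by=coded_by, nucleotide=nucleotide,
        bold_xref=None,
        hit_rows=[("REP01", "WEX00001", 1.0e-50), ("REP02", "WEX00001", 1.0e-40)],
        domain_rows=[("WEX00001", POSITIVE_DOMAINS[0], 1.0e-70),
                     ("WEX00001", NEGATIVE_DOMAINS[0], 1.0e-65)],
        expected_decision="rejected", expected_reason="superiority",
    )


# ---------------------------------------------------------------------------
# serialization

def _origin_block(seq: str) -> str:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60].lower()
        groups = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    return "\n".join(lines)


def _protein_flat(rec: FixtureRecord) -> str:
    taxonomy = "; ".join(rec.lineage) + "."
    source_extra = (
        f'                     /db_xref="{rec.bold_xref}"\n' if rec.bold_xref else ""
    )
    return (
        f"LOCUS       {rec.accession:<16}{len(rec.protein):>12} aa"
        f"            linear   INV 01-JAN-2017\n"
        f"DEFINITION  cytochrome c oxidase subunit I, partial (mitochondrion)"
        f" [{rec.binomial}].\n"
        f"ACCESSION   {rec.accession}\n"
        f"VERSION     {rec.accession}.1\n"
        f"DBSOURCE    accession {rec.nuc_accession}.1\n"
        f"SOURCE      mitochondrion {rec.binomial}\n"
        f"  ORGANISM  {rec.binomial}\n"
        f"            {taxonomy}\n"
        f"FEATURES             Location/Qualifiers\n"
        f"     source          1..{len(rec.protein)}\n"
        f'                     /organism="{rec.binomial}"\n'
        f'                     /organelle="mitochondrion"\n'
        f"{source_extra}"
        f"     Protein         1..{len(rec.protein)}\n"
        f'                     /product="cytochrome c oxidase subunit I"\n'
        f"     CDS             1..{len(rec.protein)}\n"
        f'                     /gene="COX1"\n'
        f'                     /coded_by="{rec.coded_by}"\n'
        f"                     /transl_table=5\n"
        f"ORIGIN      \n"
        f"{_origin_block(rec.protein)}\n"
        f"//\n"
    )


def _nucleotide_flat(rec: FixtureRecord) -> str:
    taxonomy = "; ".join(rec.lineage) + "."
    return (
        f"LOCUS       {rec.nuc_accession:<16}{len(rec.nucleotide):>12} bp"
        f"    DNA     linear   INV 01-JAN-2017\n"
        f"DEFINITION  {rec.binomial} mitochondrial COX1 gene, partial cds.\n"
        f"ACCESSION   {rec.nuc_accession}\n"
        f"VERSION     {rec.nuc_accession}.1\n"
        f"SOURCE      mitochondrion {rec.binomial}\n"
        f"  ORGANISM  {rec.binomial}\n"
        f"            {taxonomy}\n"
        f"FEATURES             Location/Qualifiers\n"
        f"     source          1..{len(rec.nucleotide)}\n"
        f'                     /organism="{rec.binomial}"\n'
        f"ORIGIN      \n"
        f"{_origin_block(rec.nucleotide)}\n"
        f"//\n"
    )


def write_corpus(corpus: FixtureCorpus, out_dir) -> Dict[str, Path]:
    """Serialize the corpus to its six files; byte-identical per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_fasta": out / "corpus_proteins.fasta",
        "genbank": out / "corpus.gb",
        "hits": out / "hits.tsv",
        "domain_hits": out / "domain_hits.tsv",
        "class_map": out / "class_map.tsv",
        "truth": out / "truth.tsv",
    }
    with paths["protein_fasta"].open("w") as fh:
        for rec in corpus.records:
            fh.write(f">{rec.accession} {rec.category}\n{rec.protein}\n")
    with paths["genbank"].open("w") as fh:
        for rec in corpus.records:
            fh.write(_protein_flat(rec))
        for rec in corpus.records:
            fh.write(_nucleotide_flat(rec))
    with paths["hits"].open("w") as fh:
        for rec in corpus.records:
            for query, subject, e in rec.hit_rows:
                fh.write(_tab_row(query, subject, e))
    with paths["domain_hits"].open("w") as fh:
        for rec in corpus.records:
            for cand, domain, e in rec.domain_rows:
                fh.write(_tab_row(cand, f"CDD:{domain}", e))
    with paths["class_map"].open("w") as fh:
        for d in POSITIVE_DOMAINS:
            fh.write(f"{d}\tpositive\n")
        for d in NEGATIVE_DOMAINS:
            fh.write(f"{d}\tnegative\n")
        for d in UNINFORMATIVE_DOMAINS:
            fh.write(f"{d}\tuninformative\n")
    with paths["truth"].open("w") as fh:
        fh.write("id\tcategory\texpected_decision\texpected_reason\n")
        for rec in corpus.records:
            fh.write(f"{rec.accession}\t{rec.category}\t"
                     f"{rec.expected_decision}\t{rec.expected_reason}\n")
    return paths


def _tab_row(query: str, subject: str, e_value: float) -> str:
    return "\t".join([query, subject, "90.0", "100", "5", "0", "1", "100",
                      "1", "100", f"{e_value:.3e}", "200.0"]) + "\n"


def read_truth(path) -> Dict[str, Tuple[str, str, str]]:
    """Read the truth TSV: id -> (category, expected_decision, reason)."""
    truth = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            rid, cat, dec, reason = line.rstrip("\n").split("\t")
            truth[rid] = (cat, dec, reason)
    return truth


# ---------------------------------------------------------------------------
# training-point generator

def generate_training_points(
    n_pos: int,
    n_neg: int,
    separation: float,
    seed: int = 0,
    spread: float = 1.0,
) -> Tuple[List[TrainingPoint], Optional[Tuple[Tuple[float, float], Tuple[float, float]]]]:
    """Two Gaussian clusters in (quality, superiority) space.

    Positives center at ``(20 + separation, separation)``, negatives at
    ``(20, -separation)``, both with isotropic ``spread``.  When the
    clusters do not overlap on either axis the analytically-known zero-error
    region — the open interval of workable cutoffs per axis — is returned,
    otherwise ``None``.
    """
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    pos = rng.normal([20 + separation, separation], spread, size=(n_pos, 2))
    neg = rng.normal([20, -separation], spread, size=(n_neg, 2))
    points = [
        TrainingPoint(f"pos{i}", float(q), float(s), "positive")
        for i, (q, s) in enumerate(pos)
    ] + [
        TrainingPoint(f"neg{i}", float(q), float(s), "negative")
        for i, (q, s) in enumerate(neg)
    ]
    region = None
    # Workable cutoffs: every negative must fail at least one axis while
    # every positive passes both.  The simple sufficient case recorded here
    # is full separation on the superiority axis with quality separable too.
    q_gap = (float(neg[:, 0].max()), float(pos[:, 0].min()))
    s_gap = (float(neg[:, 1].max()), float(pos[:, 1].min()))
    if s_gap[0] < s_gap[1] and q_gap[0] < q_gap[1]:
        region = (q_gap, s_gap)
    return points, region
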