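"""Flat-file parsing, coded_by locations, CDS extraction, output formats."""

import pytest
from Bio.Seq import Seq

from coiminer import fixtures, genbank_extract
from coiminer.genbank_extract import (
    Location,
    NucleotideUnavailableError,
    SeqRecordGB,
    UnsupportedLocationError,
    detect_bold,
    extract_cds,
    format_location,
    make_defline,
    parse_flatfile,
    parse_location,
    write_outputs,
)


class TestParseLocation:
    @pytest.mark.parametrize(
        "text, ref, segments, strand",
        [
            ("AB123456.1:1..658", "AB123456.1", [(0, 658)], "+"),
            ("complement(10..18)", None, [(9, 18)], "-"),
            ("complement(join(1..6,10..12))", None, [(0, 6), (9, 12)], "-"),
            ("join(N1.1:10..20,30..40)", "N1.1", [(9, 20), (29, 40)], "+"),
            ("5..9", None, [(4, 9)], "+"),
        ],
    )
    def test_coordinate_conversion(self, text, ref, segments, strand):
        loc = parse_location(text)
        assert loc.ref_accession == ref
        assert loc.segments == segments
        assert loc.strand == strand

    def test_partial_markers_set_flags(self):
        loc = parse_location("<1..658")
        assert loc.partial_5p and not loc.partial_3p
        loc = parse_location("A1.1:2..>90")
        assert loc.partial_3p and not loc.partial_5p

    @pytest.mark.parametrize("text", ["order(1..3,5..7)", "1^2", "bond(3..4)"])
    def test_unsupported_constructs_rejected_by_name(self, text):
        with pytest.raises(UnsupportedLocationError, match="unsupported"):
            parse_location(text)

    def test_garbage_rejected(self):
        with pytest.raises(UnsupportedLocationError):
            parse_location("not-a-location")

    @pytest.mark.parametrize(
        "text",
        ["AB123456.1:1..658", "complement(10..18)", "join(1..6,10..12)",
         "complement(join(1..6,10..12))", "<1..658", "2..>90"],
    )
    def test_round_trip(self, text):
        loc = parse_location(text)
        assert parse_location(format_location(loc)) == loc

    def test_invalid_segment_geometry_rejected(self):
        with pytest.raises(ValueError):
            Location(ref_accession=None, segments=[(5, 5)])
        with pytest.raises(ValueError):
            Location(ref_accession=None, segments=[(10, 20), (0, 6)])
        with pytest.raises(ValueError):
            Location(ref_accession=None, segments=[(0, 10), (5, 15)])


class TestExtractCds:
    STORE = {"N1": "AACGTT"}

    def test_simple_range(self):
        assert extract_cds(parse_location("2..4"), self.STORE) == "ACG"

    def test_reverse_complement_on_minus_strand(self):
        got = extract_cds(parse_location("complement(1..6)"), self.STORE)
        # independent oracle for the reverse complement
        assert got == str(Seq("AACGTT").reverse_complement())

    def test_join_concatenates_ascending_segments(self):
        store = {"N2": "AAACCCGGGTTT"}
        loc = parse_location("join(N2:1..3,10..12)")
        assert extract_cds(loc, store) == "AAATTT"

    def test_complement_of_join_revcomps_the_concatenation(self):
        store = {"N2": "AAACCCGGGTTT"}
        loc = parse_location("complement(join(N2:1..3,10..12))")
        assert extract_cds(loc, store) == str(Seq("AAATTT").reverse_complement())

    def test_versioned_accession_matches_unversioned_store(self):
        assert extract_cds(parse_location("N1.1:1..3"), self.STORE) == "AAC"

    def test_missing_accession_raises_unavailable(self):
        with pytest.raises(NucleotideUnavailableError):
            extract_cds(parse_location("GHOST.1:1..3"), self.STORE)

    def test_out_of_bounds_segment_raises(self):
        with pytest.raises(ValueError, match="out of bounds"):
            extract_cds(parse_location("N1.1:1..99"), self.STORE)


FLATFILE = """\
LOCUS       TP00001                    4 aa            linear   INV 01-JAN-2017
DEFINITION  test protein.
ACCESSION   TP00001
VERSION     TP00001.1
DBSOURCE    accession TN00001.1
SOURCE      mitochondrion Watersipora subtorquata
  ORGANISM  Watersipora subtorquata
            Eukaryota; Metazoa; Bryozoa.
FEATURES             Location/Qualifiers
     source          1..4
                     /organism="Watersipora subtorquata"
                     /db_xref="BOLD:AAA123.COI-5P"
     Protein         1..4
                     /product="cytochrome c oxidase subunit I"
     CDS             1..4
                     /coded_by="TN00001.1:1..15"
                     /transl_table=5
ORIGIN
        1 mkvl
//
LOCUS       TP00002                    4 aa            linear   INV 01-JAN-2017
DEFINITION  test protein without CDS link.
ACCESSION   TP00002
VERSION     TP00002.1
SOURCE      Arabidopsis thaliana
  ORGANISM  Arabidopsis thaliana
            Eukaryota; Viridiplantae.
FEATURES             Location/Qualifiers
     source          1..4
                     /organism="Arabidopsis thaliana"
ORIGIN
        1 mkvl
//
"""


class TestParseFlatfile:
    def test_fields_extracted(self):
        recs = parse_flatfile(FLATFILE)
        assert len(recs) == 2
        r = recs[0]
        assert r.accession == "TP00001"
        assert r.sequence == "MKVL"
        assert r.product == "cytochrome c oxidase subunit I"
        assert r.lineage == ["Eukaryota", "Metazoa", "Bryozoa"]
        assert r.binomial == "Watersipora subtorquata"
        assert r.coded_by == "TN00001.1:1..15"
        assert r.dbsource == "accession TN00001.1"
        assert "BOLD:AAA123.COI-5P" in r.source_feature

    def test_record_without_coded_by_is_not_an_error(self):
        recs = parse_flatfile(FLATFILE)
        assert recs[1].coded_by is None

    def test_generated_corpus_parses_cleanly(self, default_corpus, corpus_paths):
        recs = parse_flatfile(corpus_paths["genbank"])
        assert len(recs) == 2 * len(default_corpus.records)


class TestDetectBold:
    def rec(self, source=None, dbsource=None):
        return SeqRecordGB(accession="x", sequence="M",
                           source_feature=source, dbsource=dbsource)

    def test_bold_xref_with_coi_detected(self):
        assert detect_bold(self.rec(source='/db_xref="BOLD:AAA123.COI-5P"'))

    def test_bold_xref_without_coi_not_detected(self):
        assert not detect_bold(self.rec(source='/db_xref="BOLD:AAA123"'))

    def test_no_xref_not_detected(self):
        assert not detect_bold(self.rec(source='/organism="Apis mellifera"'))

    def test_dbsource_also_scanned(self):
        assert detect_bold(self.rec(dbsource='/db_xref="BOLD:XYZ.COI-3P"'))


class TestWriteOutputs:
    def test_defline_format(self):
        line = make_defline("P1", "Watersipora subtorquata", ["Metazoa", "Bryozoa"])
        assert line == "P1__Watersipora;subtorquata__Metazoa;Bryozoa"

    def test_missing_binomial_renders_empty_field(self):
        assert make_defline("P1", None, ["Metazoa"]) == "P1____Metazoa"

    def test_output_trio(self, tmp_path):
        recs = parse_flatfile(FLATFILE)
        store = {"TN00001": "ATGAAAGTATTATAA"}
        counts = write_outputs(
            recs, store, tmp_path / "p.fasta", tmp_path / "n.fasta",
            tmp_path / "acc.csv",
        )
        protein_lines = (tmp_path / "p.fasta").read_text().splitlines()
        # single-line sequences: defline/sequence pairs
        assert len(protein_lines) == 2 * counts["proteins"]
        csv_lines = (tmp_path / "acc.csv").read_text().splitlines()
        assert len(csv_lines) == counts["proteins"]
        assert csv_lines[0] == "TP00001,TN00001.1"
        assert csv_lines[1] == "TP00002,n/a"
        nuc_lines = (tmp_path / "n.fasta").read_text().splitlines()
        assert nuc_lines[1] == "ATGAAAGTATTATAA"


class TestFixtureTranslationConsistency:
    def test_extracted_cds_translates_to_protein(self, default_corpus):
        """Covers plain, complement, join and complement(join) coded_by."""
        store = {r.nuc_accession: r.nucleotide for r in default_corpus.records}
        styles = set()
        for rec in default_corpus.records:
            loc = parse_location(rec.coded_by)
            styles.add((loc.strand, len(loc.segments)))
            cds = extract_cds(loc, store)
            protein = str(Seq(cds).translate(table=5)).rstrip("*")
            assert protein == rec.protein, rec.accession
        assert styles == {("+", 1), ("-", 1), ("+", 2), ("-", 2)}
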