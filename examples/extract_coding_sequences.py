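"""Extract coding sequences from GenBank records via coded_by locations.

Accepted protein records point at their nucleotide origin through the CDS
feature's /coded_by qualifier.  The location grammar covers simple ranges,
complement (minus strand) and join (segmented) forms; extraction
concatenates segments and reverse-complements on the minus strand.
"""

from Bio.Seq import Seq

from coiminer import extract_cds, parse_location
from coiminer.genbank_extract import make_defline

nuc_store = {"NUC0001.1": "AACGGATGAAAGTATTATAAACCT"}

for text in ("NUC0001.1:5..16",
             "complement(NUC0001.1:5..16)",
             "join(NUC0001.1:5..10,14..16)"):
    loc = parse_location(text)
    cds = extract_cds(loc, nuc_store)
    print(f"{text:35s} -> {cds}")

# translation under the invertebrate mitochondrial code (NCBI table 5)
cds = extract_cds(parse_location("NUC0001.1:5..16"), nuc_store)
print(f"translated (table 5): {Seq(cds).translate(table=5)}")

# published defline format: accession__binomial__taxonomy, all
# double-underscore delimited, semicolons within fields
print(make_defline("P0001", "Watersipora subtorquata",
                   ["Eukaryota", "Metazoa", "Bryozoa"]))
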