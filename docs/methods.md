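# Methods

## Model and procedure

`coiminer` classifies candidate protein sequences as COI / not-COI using
two statistics computed from search E-values, each guarding one failure
mode of homology-based mining:

* **Quality** (sensitivity): for a subject *s* with homology-search hits
  from the representative query set, quality(s) = −log₁₀ min E. A high
  quality means *at least one* representative finds *s* convincingly;
  it deliberately ignores how many queries hit, so a single divergent
  representative suffices to recover a rare lineage.
* **Superiority** (specificity): with each conserved-domain model
  curated as *positive* (diagnostic of COI), *negative* (diagnostic of a
  different gene) or *uninformative*, superiority = −log₁₀E(best
  positive match) − (−log₁₀E(best negative match)). It measures by how
  many decades of significance the COI signal beats the best competing
  gene signal, which is what separates true COI from COX2/CYTB/ND
  paralogs and from numts that have drifted toward another gene model.

A candidate is accepted when quality > 0.9 **and** superiority > 5 (the
strict operating point), then must be ≥ 95 aa and carry `Metazoa` in its
lineage. The relaxed pair (0, −20) exists only to enumerate near-miss
records for false-negative estimation; because acceptance is monotone in
both thresholds, the strict accepted set is always a subset of the
relaxed one.

Assumptions worth making explicit: E-values from the two searches are
comparable on a log scale; the domain class map is correct (an
off-target domain misfiled as positive poisons superiority); lineage
strings are trustworthy enough for a substring taxon filter; and
injected candidates (records added after the sensitivity phase from an
external curated collection) are legitimate candidates even though they
were never search subjects — they bypass the quality test only.

## Numerical choices

* **"Exceeds" is strict `>`** (configurable to `≥`). A candidate whose
  superiority is exactly 5 is rejected at the strict threshold.
* **E = 0 / underflow** maps to a score cap of 300 (configurable):
  bounded, and above any plausible threshold.
* **E > 1 clamps to score 0**, keeping quality non-negative; the two
  sides of superiority share the clamp.
* **A missing domain class contributes 0** (the score of E = 1,
  configurable via `missing_evalue`): a candidate with no negative-class
  match gets superiority equal to its positive score, and a candidate
  with no domain hits at all gets 0 — rejected at strict, accepted at
  relaxed.
* **Domains absent from the class map are uninformative with a logged
  warning**, not an error: domain databases contain hundreds of
  COI-adjacent models and the map is curated incrementally.
* Quality ties between equally good queries break to the
  lexicographically smallest query id, making reports order-independent.

## Threshold calibration

Candidate cutoffs per axis are the midpoints between consecutive
distinct observed scores plus a sentinel below the minimum (accepts
everything on that axis) and at the maximum (accepts nothing, under
strict `>`); this finite grid realizes every classification any real
threshold could. All pairs are evaluated; the objective is unweighted
total error (false accepts + false rejects) — with separable training
sets the optimum is zero errors and any class weighting is moot, so
weighting is left as an option rather than a default.

Ties are broken by **maximal margin**, defined per-axis: the minimum
over training points of the distance from the point's scores to either
cutoff line. This symmetric definition centres both cutoffs in their
widest gaps on separable data. (A corner-distance — Chebyshev — margin
was considered and rejected: it ties between the mid-gap corner and the
accept-everything sentinel on clean clusters, letting the secondary
smallest-thresholds tie-break pick a degenerate cutoff below all
observed scores.) Remaining ties go to the lexicographically smallest
(quality, superiority) pair.

Cross-validation uses stratified, seeded, shuffled folds (label-wise
round-robin after a shuffle); per fold the tuner runs on the training
folds and errors are counted on the held-out fold with the classifier's
own decision rule. N defaults to 10.

## Representative selection

Unaligned sequences are globally aligned pairwise (match +1, mismatch
−1, gap −2, linear gap cost; Needleman–Wunsch via Biopython, first
co-optimal alignment taken deterministically) and p-distance is computed
over columns where neither sequence is gapped — 0 when no column is
comparable. p-distance under gap exclusion is symmetric with zero
self-distance but need not satisfy the triangle inequality, so no metric
assumptions are made downstream.

The diversity objective over a size-k subset defaults to the **sum** of
pairwise distances (smooth, the common diversity-maximization reading),
with **maximin** (minimum pairwise distance) as an option. Simulated
annealing searches subsets: uniform member↔non-member swap moves,
improving moves always accepted, worsening moves with probability
exp(Δ/T), geometric cooling t_start 1.0 → t_end 1e-4 at factor 0.95 with
100 moves per temperature (~18,000 moves). That budget reproduces the
enumerated optimum on every tested instance with C(n,k) ≤ 10,000; the
schedule is a dataclass, so larger populations can buy more moves.

## GenBank extraction

Locations are held internally as 0-based half-open segments with
conversion only at the parse/format boundary, eliminating off-by-one
risks in segment arithmetic. The supported `coded_by` grammar is
`a..b`, `acc.ver:a..b`, `complement(...)`, `join(...)`,
`complement(join(...))` and the partial markers `<`/`>`; anything else
(`order(...)`, `a^b`) raises an explicit unsupported-construct error
rather than guessing. `complement(join(a,b))` concatenates the
ascending segments first and reverse-complements the result (IUPAC
aware). Versioned accessions fall back to their unversioned form when
resolving nucleotide records.

Output deflines are `accession__binomial__taxonomy` with double
underscores between fields and semicolons within them; a record with
only a higher-level identification keeps an empty binomial field rather
than being dropped. Sequences are written single-line so a
`grep -A 1 taxon` retrieves complete records, and the accession CSV
writes `n/a` when no nucleotide record resolves. Translation checks
default to the invertebrate mitochondrial code (NCBI table 5),
configurable by table number.

## Validation statistics

FP rate = non-target-annotated / all accepted; FN rate =
target-annotated / all relaxed-only records, both as percentages with
ambiguous annotations kept in the denominator (a flag excludes them).
Annotation calls are an input table — the package does not infer them
from annotation text, which is curator work. The heat grid uses
half-open bins `[edge, edge + width)` (edge points land in the higher
bin) and conserves counts; the score regression is ordinary least
squares of superiority on quality, reporting slope, intercept and r².

## The synthetic corpus

The generator emulates the *score structure* of a mined corpus, not
sequence evolution: proteins are i.i.d. random over the 20-letter
alphabet, and E-values are drawn log-uniform from per-category ranges
rather than produced by running a search tool, which keeps the suite
hermetic and fast. Default conditions: 200 targets, 50 paralogs, 30
decoys, 20 short (< 95 aa) and 20 non-metazoan records, lengths 95–220
aa (40–94 for the short class); hits to passing records at
E ∈ 10^[−50, −20], best same-class domain matches at E ∈ 10^[−80, −40],
cross-class noise at E ∈ 10^[−4, 1]. These ranges sit decades clear of
the strict (0.9, 5) thresholds on the correct side, so every record's
intended decision is forced by construction and the pipeline's confusion
matrix against the recorded truth must be diagonal. Each protein's
GenBank entry carries a `coded_by` cycling through the four location
styles whose extracted CDS back-translates exactly to the protein under
table 5, and a fifth of targets carry a BOLD `db_xref` for provenance
detection. An optional record embeds the canonical worked scores
(quality 50, superiority exactly 5).

What passing on this corpus does *not* show: robustness to scores near
the thresholds (real corpora straddle them; that regime is exercised by
the threshold-tuner's inseparable-cluster tests instead), to correlated
E-values between related records, to realistic lineage noise, or to
numts with biologically faithful divergence patterns.

The training-point generator draws two isotropic Gaussian clusters in
(quality, superiority) space with a controllable separation; when the
clusters are disjoint on both axes it records the analytic zero-error
cutoff region for verification.

## Problem sizes

The test suite runs the full pipeline on the 320-record default corpus,
oracle-checks the tuner on twenty 50-point sets and the annealer on
twenty-two instances up to C(16,3); the whole suite completes in well
under a minute on one core. The acceptance script computes the two
worked statistics through the file readers and scoring path.

## Known limitations

* The engine consumes hit tables; it never runs BLAST/RPS-BLAST itself,
  and search parameters are out of scope.
* The taxon filter is an exact, case-sensitive name match against the
  lineage list — no taxonomy service resolution.
* Superiority inherits any curation error in the domain class map.
* The full GenBank location grammar (`order`, sites, remote gaps) is
  intentionally unsupported.
* p-distance-based selection operates on whatever alphabet it is given;
  it does not translate or codon-align first.
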