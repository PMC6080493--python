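# coiminer

Mining large protein corpora for **COI** (cytochrome c oxidase subunit I,
the standard animal DNA-barcode gene) with a two-phase, E-value-driven
classifier. Reference barcode databases need every COI record they can
get, but keyword searches over sequence annotations miss misannotated and
sparsely annotated records and admit paralogs (COX2, CYTB, ND1/ND2) and
nuclear pseudogene copies (numts). `coiminer` instead classifies on two
sequence-similarity statistics and only falls back to annotations to
*measure* its own error rates.

## The method

For a candidate protein *s*, given homology-search hits from a diverse
set of representative COI queries, the **sensitivity phase** computes

> quality(s) = −log₁₀ (min E-value over all hits to *s*)

and retains *s* when quality exceeds a threshold (default 0.9). Matches
against a conserved-domain database then drive the **specificity phase**:

> superiority(s) = −log₁₀ E(best COI-class domain match) −
> (−log₁₀ E(best off-target-class domain match))

the signed difference of the −log₁₀ E-values of the best
positive-class and best negative-class domain match. *s* is classified as
COI when superiority exceeds its threshold (default 5). Two hits at
E = 1.0e-50 and 1.0e-40 give quality 50; a positive match at 1.0e-70
against a negative match at 1.0e-65 gives superiority 5. Finally,
records shorter than 95 aa or without `Metazoa` in their lineage are
rejected.

Around this core the package provides:

* **representative selection** — pick *k* sequences per phylum of
  approximately maximum mutual p-distance by simulated annealing
  (`repselect`);
* **threshold calibration** — exhaustive search of the achievable
  (quality, superiority) cutoffs on labeled training sets, verified by
  stratified N-fold cross-validation (`threshold_tuner`);
* **GenBank plumbing** — flat-file parsing, `coded_by` location grammar
  (complement/join/partial), CDS extraction, BOLD `db_xref` detection and
  the published output formats (`genbank_extract`);
* **validation statistics** — annotation-conditioned FP/FN rates, the
  quality×superiority heat grid and the quality~superiority regression
  (`validation`);
* **a synthetic corpus generator** with recorded ground truth, so the
  whole pipeline is testable without any network access (`fixtures`).

## Worked example

```python
from coiminer import Thresholds, compute_quality, compute_superiority, decide

hits = [("rep1", "subject1", 1.0e-50), ("rep2", "subject1", 1.0e-40)]
quality = compute_quality(hits, "subject1")

class_map = {"COX1_dom": "positive", "COX2_dom": "negative"}
superiority = compute_superiority(
    [("COX1_dom", 1.0e-70), ("COX2_dom", 1.0e-65)], class_map
)
print(quality.score, superiority.score)
print(decide(quality.score, superiority.score, Thresholds.strict()))
```

prints

```
50.0 5.0
Decision(accepted=False, reason='superiority')
```

The subject's quality (50) comes from its best hit (E = 1.0e-50); its
superiority is the 5-decade E-value margin of the COI domain over the
COX2 domain. At strict thresholds the candidate is *rejected* —
superiority must strictly exceed 5 — while `Thresholds.relaxed()`
(0, −20), used only for false-negative bookkeeping, accepts it.

The `examples/` directory holds one short script per capability
(scoring, representative selection, tuning, end-to-end classification,
CDS extraction, validation statistics); each prints the numbers it
computes and a line on what they mean. An equivalent CLI is installed as
`coiminer` with subcommands `classify`, `select-reps`, `tune`,
`validate`, `extract` and `make-fixtures`.

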