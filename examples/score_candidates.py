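"""Score candidates with the quality and superiority statistics.

Quality is the -log10 of the smallest E-value among all homology-search
hits to a subject; superiority is the -log10 E-value of the best
target-gene conserved-domain match minus that of the best off-target
match.  A candidate is accepted when both exceed their thresholds
(strict: 0.9 and 5).
"""

from coiminer import Thresholds, compute_quality, compute_superiority, decide

# two representative queries hit the same subject
hits = [("rep1", "subject1", 1.0e-50), ("rep2", "subject1", 1.0e-40)]
quality = compute_quality(hits, "subject1")
print(f"quality          = {quality.score:g}   (best query: {quality.best_query_id})")

# the subject matches a COI domain and, more weakly, a COX2 domain
class_map = {"COX1_dom": "positive", "COX2_dom": "negative"}
superiority = compute_superiority(
    [("COX1_dom", 1.0e-70), ("COX2_dom", 1.0e-65)], class_map
)
print(f"superiority      = {superiority.score:g}   "
      f"({superiority.best_positive_domain} vs {superiority.best_negative_domain})")

for thresholds in (Thresholds.strict(), Thresholds.relaxed()):
    d = decide(quality.score, superiority.score, thresholds)
    verdict = "accept" if d.accepted else f"reject ({d.reason})"
    print(f"decision @ {thresholds.label:7s} = {verdict}")

# A superiority of exactly 5 fails the strict cutoff (5 is not > 5) but
# clears the relaxed one (-20): the margin between the best on- and
# off-target domain matches is what separates COI from its paralogs.
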