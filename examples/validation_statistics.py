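"""Validation statistics: error rates, score heat map, score regression.

False-positive and false-negative rates are conditioned on annotation
accuracy: decisions are compared against per-record annotation calls
(target / non_target / ambiguous), with ambiguous calls kept in the
denominator.
"""

import numpy as np

from coiminer import fn_rate, fp_rate, heat_grid, regression_r2

# the accepted set: mostly target-annotated, a few non-target and ambiguous
annotations = {}
accepted = []
for i in range(9_950):
    annotations[f"t{i}"] = "target"; accepted.append(f"t{i}")
for i in range(3):
    annotations[f"n{i}"] = "non_target"; accepted.append(f"n{i}")
for i in range(47):
    annotations[f"a{i}"] = "ambiguous"; accepted.append(f"a{i}")

fp = fp_rate(accepted, annotations)
print(f"false positive rate: {fp.formatted()} "
      f"({fp.n_non_target} non-target of {fp.total} accepted)")

# near-miss records (accepted only at relaxed thresholds), few true COI
relaxed_only = []
for i in range(12):
    annotations[f"fn{i}"] = "target"; relaxed_only.append(f"fn{i}")
for i in range(4_800):
    annotations[f"r{i}"] = "non_target"; relaxed_only.append(f"r{i}")
fn = fn_rate(relaxed_only, annotations)
print(f"false negative rate: {fn.formatted()} "
      f"({fn.n_target} target of {fn.total} near-misses)")

# quality and superiority carry nearly independent information
rng = np.random.default_rng(0)
quality = rng.uniform(0, 150, size=5_000)
superiority = rng.normal(30, 25, size=5_000) + 0.05 * quality
points = list(zip(quality, superiority))
slope, intercept, r2 = regression_r2(points)
print(f"superiority ~ quality: slope={slope:.3f}, r^2={r2:.3f}")

grid = heat_grid(points, bin_width_q=25.0, bin_width_s=25.0)
print(f"heat grid: {grid.counts.shape[0]}x{grid.counts.shape[1]} bins, "
      f"{grid.total()} points binned")

# A low r^2 is the point: if quality predicted superiority there would be
# no need for a two-statistic classifier.
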