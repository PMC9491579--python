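"""Weighted methylation levels from per-cytosine calls.

Simulates allc-style bisulfite calls for a handful of transposons, computes
each transposon's weighted CHG methylation level (sum of methylated reads
over sum of total reads), averages covered transposons into a per-line
trait value, and classifies transposons into RdDM- vs CMT2-target sets
from mutant methylation loss.
"""

from methgwas import (
    classify_te_targets,
    feature_levels,
    line_average,
    simulate_methylation_calls,
)
from methgwas.methylation import FeatureAnnotation

tes = [FeatureAnnotation(f"TE{i}", "Chr1", i * 2000, i * 2000 + 800) for i in range(6)]
true_levels = [0.55, 0.40, 0.25, 0.10, 0.70, 0.35]

calls = simulate_methylation_calls(tes, true_levels, depth=25, seed=1, sites_per_feature=40)
levels = feature_levels(calls, tes, context="CHG")
print("per-TE weighted mCHG (estimate vs truth):")
for te, truth in zip(tes, true_levels):
    est = levels[te.id]
    print(f"  {te.id}: {est:.3f}  (simulated at {truth:.2f})")
print(f"line average over covered TEs: {line_average(levels):.3f}")
print("  -> this is the per-line trait value the GWAS stages consume\n")

# target classes: a TE is CMT2- (RdDM-) targeted if knocking out cmt2
# (drm1 drm2) drops its methylation by more than 0.1
wt = {"TE1": 0.60, "TE2": 0.55, "TE3": 0.50}
cmt2 = {"TE1": 0.20, "TE2": 0.50, "TE3": 0.45}
drm = {"TE1": 0.55, "TE2": 0.15, "TE3": 0.45}
sets = classify_te_targets(wt, cmt2, drm)
print(f"CMT2-targeted: {sorted(sets.cmt2_ids)}  (lost >0.1 in cmt2)")
print(f"RdDM-targeted: {sorted(sets.rddm_ids)}  (lost >0.1 in drm1 drm2)")
print("TE3 lost <=0.1 in both mutants, so it stays unclassified")
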