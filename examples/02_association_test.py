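"""Test whether pairwise associations depend on spatial conditioning.

Builds 28-partition profiles from a synthetic ROI table, then compares
each pair's Pearson correlation and mutual information against null
distributions obtained by scrambling one profile along the spatial axis
1000 times (the analysis default is 100,000; reduced here for a quick
demonstration).  A pair is flagged when its statistic exceeds the 99 %
threshold of its own null.
"""

from epiderk import (
    SynthConfig,
    associate_all,
    condition_samples,
    partition_aggregate,
    synth_roi_table,
)

cond = condition_samples(synth_roi_table(SynthConfig(seed=2, samples_per_patient=300)))
profiles = partition_aggregate(cond, scheme="fine28")
results = associate_all(profiles, n_perm=1000, seed=0)

print(f"{len(results)} pairs tested (n_perm=1000, 99% thresholds):")
for r in results:
    mark = "*" if (r.significant_pearson or r.significant_mi) else " "
    print(f"{mark} {r.pair[0]:22s} vs {r.pair[1]:22s} "
          f"r={r.pearson_r:+.3f} (p={r.p_pearson:.4f})  "
          f"MI={r.mutual_info:.3f} bits (p={r.p_mi:.4f})")
# Targets sharing the generator's rise-then-drop depth trend show strong
# positive correlations and high MI with p ~ 1e-3, while the scrambled
# nulls center near r = 0 — spatial position carries the association.
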