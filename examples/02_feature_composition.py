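"""Feature composition of the constrained genome across CNC deciles.

Assigns each constrained bin a single genomic feature by priority
(coding-first), tallies compositions per CNC decile, and tests the extreme
deciles against each other with a Yates-corrected chi-squared. On the real
annotation this is where coding exons show a ~27-fold depletion and
regulatory features a several-fold enrichment in the top decile; here the
synthetic enhancers covering the planted blocks play that role.
"""

import numpy as np

from cncr import (
    FeatureHierarchy,
    SimConfig,
    annotate,
    assign_features,
    bin_track,
    compose_by_decile,
    decile_feature_test,
    join_tracks,
    partition_deciles,
    score_bins,
)
from cncr.simulate import (
    FEATURE_PRIORITY,
    simulate_feature_tracks,
    simulate_layout_and_genes,
    simulate_score_tracks,
)

config = SimConfig(seed=1)
layout, genes = simulate_layout_and_genes(config)
constraint, conservation, truth = simulate_score_tracks(config, layout, genes)
joined, _ = join_tracks(bin_track(constraint), bin_track(conservation))
scored, annotation = annotate(score_bins(joined), layout, nonconserved_rank="derive")

features = simulate_feature_tracks(config, layout, genes, truth)
hierarchy = FeatureHierarchy(tuple((lab, features[lab]) for lab in FEATURE_PRIORITY))

constrained = scored.loc[scored["constrained"]].reset_index(drop=True)
assigned = assign_features(constrained, hierarchy)
deciles = partition_deciles(constrained, np.ones(len(constrained), bool), layout)
table = compose_by_decile(assigned, deciles)

print("feature proportions, lowest vs highest CNC decile:")
for feature in table.proportions.columns:
    lo = table.proportions.at["0-10", feature]
    hi = table.proportions.at["90-100", feature]
    print(f"  {feature:12s}  0-10: {lo:6.3f}   90-100: {hi:6.3f}")

res = decile_feature_test(table, "enhancer")
print(f"\nenhancer enrichment (90-100 vs 0-10): {res['fold']:.2f}-fold, "
      f"chi2 = {res['chi2']:.1f}, p = {res['p']:.3g}")
print("a fold > 1 with small p reproduces the regulatory enrichment pattern "
      "of high-CNC territory")
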