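"""Intron-retention usage: quantification, group contrasts, dosage model.

Simulates a 600-sample cohort for a six-exon gene with a retained intron 3
(the APOE-like configuration), quantifies the normalised coverage-to-junction
usage ratio per sample, compares merged Braak stages, and fits the
covariate-adjusted linear model against e4 allele dosage. The planted dosage
effect is 0.1 per allele on the usage-ratio scale.
"""

from cncr import (
    SimConfig,
    compare_groups,
    covariate_adjusted_association,
    leave_one_group_out,
    merge_braak,
    quantify_cohort,
)
from cncr.simulate import simulate_ir_cohort

cohort = simulate_ir_cohort(SimConfig(seed=11))
quants, excluded = quantify_cohort(cohort.signals, cohort.model)
print(f"quantified {len(quants)} samples ({len(excluded)} excluded); "
      f"mean usage ratio {quants['ratio'].mean():.3f}")

quants["braak_merged"] = quants["braak"].map(merge_braak)
omnibus = compare_groups(quants, "braak_merged")
print(f"\nKruskal-Wallis across merged Braak stages: H = {omnibus.statistic:.1f}, "
      f"p = {omnibus.p:.3g}")
print(omnibus.pairwise.to_string(index=False))
print("usage rises with pathological stage because a Braak effect is planted")

model = covariate_adjusted_association(
    quants, "dosage",
    covariates=("braak", "batch", "rin", "pmi", "age_death", "sex"),
    categorical=("braak", "batch", "sex"))
print(f"\ne4 dosage slope: {model.slope:.4f} (planted 0.1), "
      f"p = {model.p:.2g}, adjusted r2 = {model.adj_r2:.3f}")

logo = leave_one_group_out(quants, "dosage", covariates=("braak",),
                           categorical=("braak",), group_col="batch")
spread = logo["slope"].max() - logo["slope"].min()
print(f"\nleave-one-batch-out: {len(logo)} refits, slope spread {spread:.4f} "
      "(homogeneous batches; no single batch drives the association)")
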