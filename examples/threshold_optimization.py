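"""Recovering a decision threshold and separating variant groups.

Sweeps every observed DS value on a noisy synthetic benchmark to find
the MCC-optimal cut-off (the planted decision boundary is 0.05), then
compares the flank abs-difference distributions of splice-altering vs
no-effect variants with Welch's t-test.
"""

from spliceland import group_compare, optimize_threshold
from spliceland.simulate import VariantDatasetSpec, gen_variant_dataset

df = gen_variant_dataset(VariantDatasetSpec(seed=0, noise_rate=0.05))

sweep = optimize_threshold(df.ds.to_numpy(), df.label.to_numpy(), criterion="max_mcc")
m = sweep.best_metrics
print(f"MCC-optimal DS threshold: {sweep.best_threshold:.4f} "
      f"(planted boundary 0.05, grid of {len(sweep.grid)} candidates)")
print(f"  at this cut-off: MCC {m.mcc:.2f}, "
      f"sensitivity {m.sensitivity:.1f}%, specificity {m.specificity:.1f}%")

g = group_compare(
    df.loc[df.true_label == 1, "abs_diff"], df.loc[df.true_label == 0, "abs_diff"]
)
print(f"\nflank abs-difference, splice-altering vs no-effect variants:")
print(f"  mean {g.mean_a:.3f} (sd {g.sd_a:.3f})  vs  mean {g.mean_b:.3f} "
      f"(sd {g.sd_b:.3f})")
print(f"  Welch t = {g.t_statistic:.1f}, two-sided p = {g.p_value:.2e}")
# spliceogenic variants sit at asymmetric SRE landscapes (high abs-diff);
# no-effect variants sit in featureless intron, hence the separation
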