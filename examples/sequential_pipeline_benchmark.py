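"""The three sequential pipelines on a planted synthetic benchmark.

Generates a labeled benchmark with the composition of the curated
literature set (133 splice-altering variants — 117 cryptic-site, 16
SRE-mechanism — and 100 without effect), classifies it in each pipeline
mode and prints the performance. Mode 1 (DS only) misses exactly the
SRE-mechanism positives; adding the ΔESRseq stage recovers them.
"""

from spliceland import ConfusionCounts, PipelineThresholds, batch_classify, metrics
from spliceland.simulate import VariantDatasetSpec, gen_variant_dataset

df = gen_variant_dataset(VariantDatasetSpec(seed=0))
truth = df.set_index("variant_id")["label"]

print("mode  description                 sens%   spec%    acc%    MCC")
for mode, desc in (
    (1, "DS >= 0.05"),
    (2, "+ dESRseq >= 0.63"),
    (3, "+ abs_diff >= 0.51"),
):
    res = batch_classify(df, PipelineThresholds(mode=mode))
    pos = {r.variant_id for r in res.records if r.is_positive}
    tp = sum(truth[v] == 1 for v in pos)
    fp = len(pos) - tp
    n_pos, n_neg = int((truth == 1).sum()), int((truth == 0).sum())
    m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp))
    print(
        f"  {mode}   {desc:25s} {m.sensitivity:6.2f}  {m.specificity:6.2f}"
        f"  {m.accuracy:6.2f}  {m.mcc:5.2f}"
    )
# on the noise-free planted set mode 3 is perfect by construction; the
# interesting structure is mode 1's sensitivity gap: 16/133 positives act
# through SREs and are invisible to the splice-site delta score alone
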