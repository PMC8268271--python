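# Methods

## Model

The framework treats pre-mRNA splice-site recognition through the
exon-definition lens: exons are enriched in enhancer SREs (ESE), introns
in silencer SREs (ISS), and an intronic region whose SRE balance looks
exon-like is a candidate for inclusion in mature mRNA as a pseudoexon.
All SRE quantities derive from a hexamer score table — one real score
per 6-mer, positive = enhancer-like, negative = silencer-like, of the
kind derived empirically from minigene screens.

**Per-nucleotide score.** Each base receives the arithmetic **mean** of
the scores of the hexamers covering it (at most 6). The covering set is
completed with up to 5 nt of flanking genomic context where available;
positions near an unpadded end use only their available windows. The
mean keeps per-nucleotide values on the hexamer scale and makes a
constant table score through exactly; because the aggregation choice is
not uniquely determined by the "area" language of the literature, a
`aggregate="sum"` switch provides the sum variant. Hexamers containing
N are dropped from a position's covering set; a position with no
scoreable window scores 0 with a logged warning (never silently for
missing table entries — sparse tables raise).

**Area and normalized SRE area.** `area = Σ per-nt scores` over a
region; `normalized area = area / length`. The normalized area is the
region's exon-likeness summary; it is invariant to splitting a region
and recombining by length-weighted average.

**Landscape contrast.** For an exon or pseudoexon, the two 100-nt
intronic flank windows (acceptor side preceding, donor side following,
in transcription order) are scored the same way and
`contrast = region − (flank_acc + flank_don)/2` in normalized-area
units. Minus-strand regions are reverse-complemented onto the sense
strand before any hexamer lookup, so scoring is strand-consistent by
construction. Exceptionally long exons are excluded from gene-level
landscape runs (`max_exon_len`, default 300 nt — most exons are
shorter); exclusions are reported, never silent.

**ΔESRseq.** For an SNV, the wild-type window is the 11-mer centred on
the variant and the variant window substitutes the alternate base; each
window is scored as the **sum of its six covering hexamers** (every
6-mer of an 11-mer contains the central base) and ΔESRseq is
variant − wild type. For indels — present in real cohorts but not
covered by the substitution recipe — the windows are the affected
reference span ±5 nt and the alternate allele ±5 nt, scored the same
way; the extension is flagged with a logged notice. ΔESRseq is
antisymmetric under ref/alt exchange.

**Flank abs-difference.** The 100-nt windows upstream and downstream of
the variant are separated from the affected span by a 5-nt gap — the
minimal separation that keeps every variant-overlapping hexamer out of
both windows (a hexamer covering a window base reaches at most 5 nt
beyond it). The gap bases serve only as edge context. The statistic is
`|Ā_up − Ā_down|`, symmetric under flank exchange and invariant under
reverse-complementing the locus together with a strand flip. 105 nt of
sequence per side are required.

**Deep intronic classification.** Distance is measured in nt from the
variant's nearest affected base to the nearest exon–intron junction
(the first intronic base adjacent to an exon has distance 1). A variant
is *deep intronic* iff it lies in an intron strictly more than 20 nt
from every junction — outside splice-site consensus sequences; at
exactly 20 nt it is near-splice intronic. The rule is strict by design.

**Sequential pipeline.** Three nested modes:
(1) positive iff `DS ≥ t_ds`;
(2) additionally positive iff `ΔESRseq ≥ t_esr` when DS fails;
(3) as 2 but the SRE branch also requires `abs-diff ≥ t_abs`.
Defaults (0.05, 0.63, 0.51) are the benchmark-optimized cut-offs. All
comparisons are inclusive (≥) — published descriptions mix "greater
than" and "equal or greater", and ≥ is adopted uniformly. The ΔESRseq
branch uses the signed value: both ISE creation and ISS disruption push
the score up. Sequentiality means a DS-positive variant never consults
the SRE statistics, so their absence is not an error for it; variants
with no DS at all are unclassifiable and reported as failures, not
negatives. Raising any score can never flip a positive to negative, and
mode-1 positives ⊆ mode-2 positives ⊇ mode-3 positives on any dataset.

## Evaluation machinery

Standard confusion metrics on the percent scale; MCC with a zero
denominator is 0 (common convention), rate metrics with a zero
denominator are null rather than 0. "False discovery rate" is reported
as `100 − PPV`. `counts_from_rates` inverts a published
(class sizes, sensitivity, specificity) row to integer counts with
half-up rounding and warns if the re-derived rates drift by more than
0.5 points — this is what lets printed benchmark tables be reconciled
exactly. Threshold optimization sweeps the sorted unique observed
scores plus one value below the minimum (`score ≥ t` ⇒ positive),
maximizing MCC or sensitivity+specificity, ties to the smallest
threshold; the grid-of-observed-values choice makes the sweep exhaustive
and deterministic. Group comparison is Welch's unequal-variance
two-sided t-test; two identical zero-variance groups return t = 0,
p = 1 rather than NaN.

The bundled benchmark summaries include two experimental-cohort rows
whose printed MCCs (0.62, 0.43) are not consistent with the confusion
counts implied by their own rates at class sizes 5/28 (those counts
give ≈0.52 and ≈0.36). The package reproduces the counts-consistent
accuracies and flags the MCC cells (`mcc_consistent=False`) instead of
matching them.

## Synthetic data

The generators emulate the *statistical structure* of the benchmark
datasets, not their sequences:

* **Tables** — ~25% enhancer hexamers (scores N(+0.3, 0.1)), ~25%
  silencer (N(−0.3, 0.1)), rest neutral (0). Classes are closed under
  cyclic rotation (whole orbits assigned per class; orbit granularity
  puts class sizes within 5 of the target), so a tandem repeat of a
  class hexamer scores in-class at every sliding window.
* **Genes** — exons tiled from enhancer-class hexamers, introns from
  silencer-class hexamers, in 24-nt tandem runs; one pseudoexon-like
  island (default 144 nt, exactly 2/3 enhancer runs, planted mid-intron)
  with intermediate bias ≈ +0.1. The run/orbit construction is what
  makes the planted exon > island > intron-flank ordering hold by
  construction (margin ≫ noise in 200/200 test seeds) rather than in
  expectation: without it, 5/6 of sliding windows straddle hexamer
  junctions and dilute the planted bias 6-fold.
* **Variant benchmarks** — 133 positives (117 cryptic-site mechanism:
  DS = 0.05 + 0.95·Beta(1.2, 3), dense just above the boundary; 16
  SRE mechanism: DS below the boundary with ΔESRseq ≥ 0.63 and
  abs-diff ≥ 0.51 from shifted exponentials) and 100 negatives below
  all three cut-offs, matching the literature cohort's composition.
  Below the 0.05 boundary, DS has the same Beta(1, 3)·0.05 shape for
  SRE positives and negatives — sub-boundary DS carries no class
  signal, so the planted boundary is the identifiable decision point
  for threshold-recovery experiments. Optional label noise flips each
  label independently. Distribution families are pragmatic choices and
  are not claimed to match any empirical score distribution.

All generators are pure functions of their spec (same seed ⇒
byte-identical output). What passing tests on this synthetic data show
is that the *arithmetic and decision logic* are correct and that the
planted structure is recovered; they say nothing about discrimination
on real variants, which depends on an empirical hexamer table and real
SpliceAI scores.

## Numerical choices and limitations

* Coordinates are 0-based half-open internally; 1-based conventions
  (VCF, HGVS-style reports) are converted exactly once at I/O.
* Report output rounds to 6 decimals; internal values are full
  precision. Published-table reconciliation uses half-up rounding to
  2 decimals.
* Per-nucleotide aggregation over covering hexamers is a documented
  open choice (mean default, sum available); ΔESRseq totals are sums.
* The SpliceAI network is never run; delta scores are inputs. No
  branch-point, polypyrimidine or protein-binding modelling; no motif
  discovery; no clinical classification.
* Problem sizes in tests and the acceptance script (233-variant
  benchmarks, 20 recovery seeds, 10 landscape seeds, 500-sequence
  oracle sweeps) were chosen to exercise the full logic at
  interactive runtimes.
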