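"""Per-variant statistics: delta score, ΔESRseq and flank abs-difference.

Three numbers summarize a candidate spliceogenic variant:

* **DS** — the splice-site delta score taken from precomputed SpliceAI
  annotations: the max of acceptor/donor *gain* scores for intronic
  variants (a new splice site creates a pseudoexon) and of acceptor/donor
  *loss* scores for exonic variants (a broken site skips an exon).
* **ΔESRseq** — the change in total hexamer SRE score over the 11-nt
  window centered on the variant (variant minus wild type): positive
  values mean the variant strengthens enhancers or weakens silencers.
* **flank abs-difference** — the absolute difference of normalized SRE
  area between the 100-nt intronic windows upstream and downstream of
  the variant (variant-affected hexamers excluded): an asymmetric SRE
  balance marks a latent exon/intron boundary near the variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .hexamers import HexamerTable, revcomp
from .landscape import GeneModel, per_nucleotide_scores, region_score

__all__ = [
    "GenomicVariant",
    "SpliceAIAnnotation",
    "VariantScoreSet",
    "RegionClass",
    "spliceai_ds",
    "delta_esrseq",
    "flank_abs_diff",
    "deep_intronic_class",
    "score_variant",
    "DEEP_INTRONIC_MIN_DISTANCE",
    "FLANK_WINDOW_LEN",
    "FLANK_GAP",
]

logger = logging.getLogger(__name__)

DEEP_INTRONIC_MIN_DISTANCE = 20  # nt; deep intronic means strictly farther
FLANK_WINDOW_LEN = 100
FLANK_GAP = 5  # bases between the affected span and each flank window

DEEP_INTRONIC = "deep_intronic"
NEAR_SPLICE = "near_splice_intronic"
EXONIC = "exonic"
RegionClass = str  # one of the three constants above
_INTRONIC_CLASSES = frozenset({DEEP_INTRONIC, NEAR_SPLICE})


@dataclass
class GenomicVariant:
    """A VCF-style variant (1-based ``pos``, non-empty ref/alt alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str = ""
    strand: str = "+"
    hgvs_c: Optional[str] = None
    region_class: Optional[RegionClass] = None
    label: Optional[str] = None  # "splice_altering" / "no_effect"

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty (VCF style)")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def start0(self) -> int:
        """0-based index of the first affected reference base."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based half-open end of the affected reference span."""
        return self.pos - 1 + len(self.ref)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class SpliceAIAnnotation:
    """Precomputed splice-site delta scores and positions for one gene.

    Delta scores are probabilities in [0, 1] that the variant gains or
    loses an acceptor/donor; ``dp_*`` are the offsets (nt, negative =
    upstream) of the affected positions within the scored window.
    """

    ds_ag: float
    ds_al: float
    ds_dg: float
    ds_dl: float
    dp_ag: int = 0
    dp_al: int = 0
    dp_dg: int = 0
    dp_dl: int = 0
    gene_id: str = ""
    window: int = 4999  # nt scanned on each side of the variant

    def __post_init__(self) -> None:
        for name in ("ds_ag", "ds_al", "ds_dg", "ds_dl"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("dp_ag", "dp_al", "dp_dg", "dp_dl"):
            if abs(getattr(self, name)) > self.window:
                raise ValueError(f"{name} exceeds scoring window ±{self.window}")


@dataclass
class VariantScoreSet:
    """The three framework statistics for one variant (None = not computable)."""

    ds: Optional[float] = None
    delta_esrseq: Optional[float] = None
    abs_diff: Optional[float] = None
    ds_positions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ds is not None and not (0.0 <= self.ds <= 1.0):
            raise ValueError(f"ds={self.ds} outside [0, 1]")
        if self.abs_diff is not None and self.abs_diff < 0:
            raise ValueError("abs_diff must be non-negative")


# ----------------------------------------------------------------------
# DS extraction
# ----------------------------------------------------------------------
def spliceai_ds(ann: SpliceAIAnnotation, region_class: RegionClass) -> float:
    """Delta score for the variant's mechanism class.

    Intronic variants (deep or near-splice) are scored by gain
    (max of acceptor-gain/donor-gain: a gained site can create a
    pseudoexon); exonic variants by loss (max of acceptor-loss/donor-loss).
    """
    if region_class in _INTRONIC_CLASSES:
        return max(ann.ds_ag, ann.ds_dg)
    if region_class == EXONIC:
        return max(ann.ds_al, ann.ds_dl)
    raise ValueError(f"unknown region class {region_class!r}")


# ----------------------------------------------------------------------
# ΔESRseq
# ----------------------------------------------------------------------
def _window_total(seq: str, table: HexamerTable) -> float:
    """Sum of the scores of all 6-mer windows of ``seq``."""
    return sum(table[seq[i : i + 6]] for i in range(len(seq) - 5))


def _check_ref(variant: GenomicVariant, genome) -> None:
    observed = genome.fetch(variant.chrom, variant.start0, variant.end0)
    if observed != variant.ref.upper():
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: variant "
            f"ref {variant.ref!r} but genome has {observed!r}"
        )


def delta_esrseq(variant: GenomicVariant, genome, table: HexamerTable) -> float:
    """Variant-minus-wild-type total hexamer score around the variant.

    For an SNV the wild-type window is the 11-mer centered on the variant
    (5 nt each side) and the variant window substitutes the alternate
    base; each window is scored as the sum of its 6 covering hexamers
    (every 6-mer of an 11-mer contains the central base). For indels the
    windows are the affected reference span ±5 nt and the alternate
    allele ±5 nt — an extension of the substitution recipe, flagged with
    a logged notice. Scoring is on the sense strand of the gene.
    """
    _check_ref(variant, genome)
    p0, q0 = variant.start0, variant.end0
    contig_len = genome.length(variant.chrom)
    if p0 - 5 < 0 or q0 + 5 > contig_len:
        raise ValueError(
            f"need 5 nt of context on each side of {variant.chrom}:{variant.pos} "
            f"(contig length {contig_len})"
        )
    left = genome.fetch(variant.chrom, p0 - 5, p0)
    right = genome.fetch(variant.chrom, q0, q0 + 5)
    wt = left + variant.ref.upper() + right
    var = left + variant.alt.upper() + right
    if not variant.is_snv:
        logger.info(
            "ΔESRseq for non-SNV %s:%d %s>%s uses the windowed-span extension",
            variant.chrom,
            variant.pos,
            variant.ref,
            variant.alt,
        )
    if variant.strand == "-":
        wt, var = revcomp(wt), revcomp(var)
    return _window_total(var, table) - _window_total(wt, table)


# ----------------------------------------------------------------------
# flank absolute difference
# ----------------------------------------------------------------------
def _flank_region(
    genome, chrom: str, start: int, end: int, strand: str, table: HexamerTable
):
    """Score flank window [start, end) with its own local context.

    Context never crosses into the variant-affected span: callers pass
    windows separated from the variant by FLANK_GAP bases, and only those
    gap bases (plus outward genomic context) complete edge hexamers.
    """
    contig_len = genome.length(chrom)
    c_start = max(0, start - FLANK_GAP)
    c_end = min(contig_len, end + FLANK_GAP)
    left = genome.fetch(chrom, c_start, start)
    seq = genome.fetch(chrom, start, end)
    right = genome.fetch(chrom, end, c_end)
    if strand == "-":
        seq = revcomp(seq)
        left, right = revcomp(right), revcomp(left)
    return region_score(
        per_nucleotide_scores(seq, table, left_context=left, right_context=right)
    )


def flank_abs_diff(
    variant: GenomicVariant,
    genome,
    table: HexamerTable,
    window_len: int = FLANK_WINDOW_LEN,
) -> float:
    """|normalized SRE area upstream − downstream| around a variant.

    Each window spans ``window_len`` nt and is separated from the
    affected reference span by a 5-nt gap, so no hexamer overlapping the
    variant enters either window; the gap bases serve only as edge
    context. Requires ``window_len + 5`` nt of sequence on each side.
    """
    _check_ref(variant, genome)
    p0, q0 = variant.start0, variant.end0
    contig_len = genome.length(variant.chrom)
    up_start = p0 - FLANK_GAP - window_len
    down_end = q0 + FLANK_GAP + window_len
    if up_start < 0 or down_end > contig_len:
        raise ValueError(
            f"flank windows for {variant.chrom}:{variant.pos} require span "
            f"[{up_start}, {down_end}) but contig has length {contig_len}"
        )
    upstream = _flank_region(
        genome, variant.chrom, up_start, p0 - FLANK_GAP, variant.strand, table
    )
    downstream = _flank_region(
        genome, variant.chrom, q0 + FLANK_GAP, down_end, variant.strand, table
    )
    return abs(upstream.normalized_area - downstream.normalized_area)


# ----------------------------------------------------------------------
# region classification
# ----------------------------------------------------------------------
def deep_intronic_class(
    variant: GenomicVariant, model: GeneModel
) -> tuple[RegionClass, int]:
    """Classify a variant as exonic / near-splice / deep intronic.

    Returns the class and the nt distance from the variant's nearest
    affected base to the nearest exon-intron junction (the first
    intronic base next to an exon has distance 1). Deep intronic means
    the variant is intronic and strictly more than 20 nt from every
    junction — outside the splice-site consensus.
    """
    span_start, span_end = model.span
    if variant.end0 <= span_start or variant.start0 >= span_end:
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} outside transcript span "
            f"[{span_start}, {span_end}) of {model.gene_id}"
        )
    exons = sorted(model.exons)
    affected = range(variant.start0, variant.end0)
    in_exon = any(s <= b < e for b in affected for s, e in exons)
    if in_exon:
        # distance to nearest junction measured within the exon
        dist = min(
            min(b - s + 1, e - b)
            for b in affected
            for s, e in exons
            if s <= b < e
        )
        return EXONIC, dist

    # junction coordinates: each exon contributes its two edges
    junction_dists = []
    for b in affected:
        for s, e in exons:
            if b < s:
                junction_dists.append(s - b)
            elif b >= e:
                junction_dists.append(b - e + 1)
    dist = min(junction_dists)
    cls = DEEP_INTRONIC if dist > DEEP_INTRONIC_MIN_DISTANCE else NEAR_SPLICE
    return cls, dist


# ----------------------------------------------------------------------
# bundling
# ----------------------------------------------------------------------
def score_variant(
    variant: GenomicVariant,
    ann: Optional[SpliceAIAnnotation],
    genome,
    table: HexamerTable,
    region_class: Optional[RegionClass] = None,
) -> VariantScoreSet:
    """Compute DS, ΔESRseq and flank abs-difference for one variant.

    Statistics that cannot be computed (e.g. no annotation) come back as
    explicit ``None``, never silent zeros.
    """
    rc = region_class or variant.region_class or DEEP_INTRONIC
    ds = None
    positions: dict[str, int] = {}
    if ann is not None:
        ds = spliceai_ds(ann, rc)
        positions = {
            "dp_ag": ann.dp_ag,
            "dp_al": ann.dp_al,
            "dp_dg": ann.dp_dg,
            "dp_dl": ann.dp_dl,
        }
    return VariantScoreSet(
        ds=ds,
        delta_esrseq=delta_esrseq(variant, genome, table),
        abs_diff=flank_abs_diff(variant, genome, table),
        ds_positions=positions,
    )
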