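"""Per-nucleotide SRE scoring and regional splicing landscapes.

The central quantity is the *normalized SRE area* of a sequence region:
each nucleotide receives the mean score of the hexamers covering it,
the per-nucleotide scores are summed over the region ("area") and the
area is divided by the region length. Exons tend to have positive
normalized area (enhancer-rich), introns negative (silencer-rich);
intronic islands with exon-like positive areas are candidate
pseudoexons. Landscapes contrast a region's normalized area against its
two 100-nt intronic flanks, mirroring the exon-definition view of
splice-site recognition.

All coordinates here are 0-based half-open on the plus strand of the
reference; minus-strand regions are reverse-complemented onto the sense
(transcribed) strand before hexamer lookup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .hexamers import HexamerTable, revcomp

__all__ = [
    "NucleotideScoreTrack",
    "RegionScore",
    "RegionLandscape",
    "GeneModel",
    "SkippedExon",
    "per_nucleotide_scores",
    "region_score",
    "region_landscape",
    "gene_landscapes",
    "exonizability_track",
]

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
CONTEXT_LEN = 5  # nt of flanking context completing edge hexamers
DEFAULT_FLANK_LEN = 100
DEFAULT_MAX_EXON_LEN = 300  # typical exons are shorter than this


def _validate_seq(seq: str, what: str = "sequence") -> None:
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise ValueError(
                f"invalid character {ch!r} at position {i} of {what}: "
                "only A/C/G/T (and N) are allowed"
            )


@dataclass
class NucleotideScoreTrack:
    """Per-nucleotide SRE scores over a region.

    ``per_nt_scores[i]`` is the aggregated hexamer score of base
    ``start + i``; length equals ``end - start``.
    """

    region_id: str
    start: int
    end: int
    per_nt_scores: np.ndarray

    def __post_init__(self) -> None:
        self.per_nt_scores = np.asarray(self.per_nt_scores, dtype=float)
        if len(self.per_nt_scores) != self.end - self.start:
            raise ValueError(
                f"track length {len(self.per_nt_scores)} != interval size "
                f"{self.end - self.start} for {self.region_id}"
            )
        if not np.all(np.isfinite(self.per_nt_scores)):
            raise ValueError(f"non-finite score in track {self.region_id}")

    def __len__(self) -> int:
        return len(self.per_nt_scores)


@dataclass(frozen=True)
class RegionScore:
    """Area (sum of per-nt scores) and normalized SRE area of a region."""

    area: float
    normalized_area: float
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("region length must be >= 1")


@dataclass(frozen=True)
class RegionLandscape:
    """A region's SRE score contrasted with its intronic flanks.

    ``contrast`` is the region's normalized area minus the mean of the
    acceptor- and donor-side flank normalized areas; exon-like regions
    have strongly positive contrast.
    """

    region_id: str
    region: RegionScore
    flank_acceptor: RegionScore
    flank_donor: RegionScore
    contrast: float


@dataclass
class GeneModel:
    """Exon structure of one transcript.

    ``exons`` are 0-based half-open genomic intervals sorted in
    transcription order (ascending coordinates on '+', descending on '-').
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon interval ({s}, {e}) in {self.gene_id}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(
                f"exons of {self.gene_id} not in transcription order for "
                f"strand {self.strand}"
            )

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) covering the whole transcript."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


@dataclass(frozen=True)
class SkippedExon:
    """Report of an exon excluded from a landscape run (never silent)."""

    gene_id: str
    exon_index: int
    start: int
    end: int
    reason: str


# ----------------------------------------------------------------------
# per-nucleotide scoring
# ----------------------------------------------------------------------
def per_nucleotide_scores(
    seq: str,
    table: HexamerTable,
    left_context: str = "",
    right_context: str = "",
    aggregate: str = "mean",
) -> np.ndarray:
    """Score each base of ``seq`` from the hexamers covering it.

    Every 6-mer window of ``left_context + seq + right_context`` that can
    be scored contributes to the 6 positions it covers. A fully flanked
    position is covered by exactly 6 hexamers; positions near an unpadded
    end use only the available windows. Up to 5 nt of each context are
    used (more is trimmed).

    Parameters
    ----------
    aggregate
        ``"mean"`` (default) keeps per-nt values on the hexamer scale;
        ``"sum"`` returns the raw sum over covering hexamers.

    Windows containing N are excluded from a position's covering set; a
    position with zero scoreable covering windows scores 0.0 with a
    logged warning. Sparse (toy) tables raise on any missing hexamer.
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError(f"aggregate must be 'mean' or 'sum', got {aggregate!r}")
    if len(seq) < 1:
        raise ValueError("sequence must contain at least 1 nucleotide")
    seq = seq.upper()
    left = left_context.upper()[-CONTEXT_LEN:] if left_context else ""
    right = right_context.upper()[:CONTEXT_LEN] if right_context else ""
    _validate_seq(seq, "sequence")
    _validate_seq(left, "left context")
    _validate_seq(right, "right context")

    padded = left + seq + right
    if len(padded) < 6:
        raise ValueError(
            f"padded sequence has {len(padded)} nt; at least 6 are needed "
            "to form one hexamer (supply context or a longer sequence)"
        )
    n_windows = len(padded) - 5
    win_score = np.zeros(n_windows)
    win_valid = np.zeros(n_windows)
    for w in range(n_windows):
        hexamer = padded[w : w + 6]
        if "N" in hexamer:
            continue
        win_score[w] = table[hexamer]
        win_valid[w] = 1.0

    kernel = np.ones(6)
    cov_sum = np.convolve(win_score, kernel)  # full: len(padded) values
    cov_cnt = np.convolve(win_valid, kernel)
    off = len(left)
    s = cov_sum[off : off + len(seq)]
    c = cov_cnt[off : off + len(seq)]
    if aggregate == "sum":
        return s
    uncovered = c == 0
    if uncovered.any():
        logger.warning(
            "%d position(s) with no scoreable covering hexamer set to 0.0",
            int(uncovered.sum()),
        )
    return np.where(uncovered, 0.0, s / np.maximum(c, 1.0))


def region_score(track: NucleotideScoreTrack | Sequence[float]) -> RegionScore:
    """Area and normalized SRE area of a per-nucleotide score track."""
    values = (
        track.per_nt_scores
        if isinstance(track, NucleotideScoreTrack)
        else np.asarray(track, dtype=float)
    )
    if len(values) == 0:
        raise ValueError("cannot score an empty track")
    area = float(values.sum())
    return RegionScore(area=area, normalized_area=area / len(values), length=len(values))


# ----------------------------------------------------------------------
# regional landscapes
# ----------------------------------------------------------------------
def _score_window(
    genome,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    table: HexamerTable,
    aggregate: str,
) -> RegionScore:
    """Score genomic window [start, end) on the sense strand of ``strand``.

    Fetches up to 5 nt of genomic context on each side (clipped at contig
    ends) so edge hexamers are completed from their true neighborhood.
    """
    contig_len = genome.length(chrom)
    if start < 0 or end > contig_len:
        raise ValueError(
            f"window {chrom}:{start}-{end} outside contig (length {contig_len})"
        )
    c_start = max(0, start - CONTEXT_LEN)
    c_end = min(contig_len, end + CONTEXT_LEN)
    left = genome.fetch(chrom, c_start, start)
    seq = genome.fetch(chrom, start, end)
    right = genome.fetch(chrom, end, c_end)
    if strand == "-":
        seq = revcomp(seq)
        left, right = revcomp(right), revcomp(left)
    track = per_nucleotide_scores(
        seq, table, left_context=left, right_context=right, aggregate=aggregate
    )
    return region_score(track)


def region_landscape(
    genome,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    table: HexamerTable,
    flank_len: int = DEFAULT_FLANK_LEN,
    region_id: str = "",
    aggregate: str = "mean",
) -> RegionLandscape:
    """Landscape of a region against its two intronic flanks.

    Scores the region and the ``flank_len``-nt windows on either side; in
    transcription order the acceptor-side flank precedes the region and
    the donor-side flank follows it (so they swap genomic sides on '-').
    ``contrast = region - mean(flanks)`` in normalized-area units.
    """
    contig_len = genome.length(chrom)
    if start - flank_len < 0 or end + flank_len > contig_len:
        raise ValueError(
            f"flanks of {chrom}:{start}-{end} (±{flank_len} nt) extend past "
            f"contig bounds [0, {contig_len})"
        )
    region = _score_window(genome, chrom, start, end, strand, table, aggregate)
    upstream = _score_window(
        genome, chrom, start - flank_len, start, strand, table, aggregate
    )
    downstream = _score_window(genome, chrom, end, end + flank_len, strand, table, aggregate)
    if strand == "+":
        flank_acc, flank_don = upstream, downstream
    else:
        flank_acc, flank_don = downstream, upstream
    contrast = region.normalized_area - 0.5 * (
        flank_acc.normalized_area + flank_don.normalized_area
    )
    return RegionLandscape(
        region_id=region_id or f"{chrom}:{start}-{end}({strand})",
        region=region,
        flank_acceptor=flank_acc,
        flank_donor=flank_don,
        contrast=contrast,
    )


def gene_landscapes(
    model: GeneModel,
    genome,
    table: HexamerTable,
    max_exon_len: int = DEFAULT_MAX_EXON_LEN,
    flank_len: int = DEFAULT_FLANK_LEN,
    aggregate: str = "mean",
) -> tuple[list[RegionLandscape], list[SkippedExon]]:
    """One landscape per exon of ``model``, skipping exceptionally long exons.

    Exons longer than ``max_exon_len`` (pass ``None`` for no limit) are
    reported in the second return value, never silently dropped.
    """
    landscapes: list[RegionLandscape] = []
    skipped: list[SkippedExon] = []
    for idx, (start, end) in enumerate(model.exons):
        length = end - start
        if max_exon_len is not None and length > max_exon_len:
            skipped.append(
                SkippedExon(
                    gene_id=model.gene_id,
                    exon_index=idx,
                    start=start,
                    end=end,
                    reason=f"length {length} nt exceeds max_exon_len {max_exon_len}",
                )
            )
            continue
        landscapes.append(
            region_landscape(
                genome,
                model.chrom,
                start,
                end,
                model.strand,
                table,
                flank_len=flank_len,
                region_id=f"{model.gene_id}:exon{idx + 1}",
                aggregate=aggregate,
            )
        )
    return landscapes, skipped


def exonizability_track(
    seq: str,
    table: HexamerTable,
    window: int,
    step: int = 1,
    aggregate: str = "mean",
) -> list[tuple[int, float]]:
    """Sliding-window normalized SRE area over ``seq``.

    Scans for intronic stretches with exon-like (positive) SRE balance —
    candidate "exonizable" regions. Returns ``(window_start,
    normalized_area)`` pairs ordered by start. Per-nucleotide scores are
    computed once over the full sequence, so interior windows see their
    true hexamer context.
    """
    if window < 6:
        raise ValueError("window must be at least 6 nt")
    if step < 1:
        raise ValueError("step must be >= 1")
    if window > len(seq):
        logger.warning(
            "window (%d nt) longer than sequence (%d nt): empty track",
            window,
            len(seq),
        )
        return []
    per_nt = per_nucleotide_scores(seq, table, aggregate=aggregate)
    csum = np.concatenate([[0.0], np.cumsum(per_nt)])
    out: list[tuple[int, float]] = []
    for start in range(0, len(seq) - window + 1, step):
        area = csum[start + window] - csum[start]
        out.append((start, float(area / window)))
    return out
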