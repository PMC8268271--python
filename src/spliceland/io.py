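"""Readers and writers for the external formats the framework touches.

Genomes are indexed FASTA (random access via pyfaidx); variant tables
are TSV or VCF with SpliceAI-style INFO annotations (parsed via pysam);
gene models come from BED12 or minimal GFF3; landscape output goes to
TSV reports and bedGraph tracks.

Coordinate conventions: VCF and the 1-based world exist only at parse
time — everything internal is 0-based half-open, converted exactly once
here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .hexamers import revcomp
from .landscape import GeneModel, RegionLandscape
from .variants import GenomicVariant, SpliceAIAnnotation

__all__ = [
    "FastaGenome",
    "DictGenome",
    "read_fasta_region",
    "read_spliceai_vcf",
    "read_variant_tsv",
    "write_scored_tsv",
    "read_scored_tsv",
    "read_bed12",
    "read_gff3_exons",
    "write_region_report",
    "write_bedgraph",
    "write_fasta",
    "NULL_TOKEN",
]

logger = logging.getLogger(__name__)

NULL_TOKEN = "."  # TSV null marker

SCORE_COLUMNS = ["ds", "delta_esrseq", "abs_diff", "region_class", "distance_to_junction"]
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "strand", "label"]


# ----------------------------------------------------------------------
# genome accessors
# ----------------------------------------------------------------------
class DictGenome:
    """In-memory genome: a mapping of contig name -> uppercase sequence."""

    def __init__(self, contigs: dict[str, str]):
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}

    def length(self, chrom: str) -> int:
        try:
            return len(self._contigs[chrom])
        except KeyError:
            raise KeyError(f"unknown contig {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        n = self.length(chrom)
        if start < 0 or end > n or start > end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} out of range (contig length {n})"
            )
        return self._contigs[chrom][start:end]

    def contigs(self) -> list[str]:
        return list(self._contigs)


class FastaGenome:
    """Random-access indexed FASTA genome (0-based half-open fetches)."""

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), sequence_always_upper=True)

    def length(self, chrom: str) -> int:
        try:
            return len(self._fasta[chrom])
        except KeyError:
            raise KeyError(f"unknown contig {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        n = self.length(chrom)
        if start < 0 or end > n or start > end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} out of range (contig length {n})"
            )
        return str(self._fasta[chrom][start:end])

    def contigs(self) -> list[str]:
        return list(self._fasta.keys())


def read_fasta_region(
    path: str | Path, chrom: str, start: int, end: int, strand: str = "+"
) -> str:
    """Fetch one region (0-based half-open), reverse-complemented on '-'."""
    seq = FastaGenome(path).fetch(chrom, start, end)
    return revcomp(seq) if strand == "-" else seq


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ----------------------------------------------------------------------
# SpliceAI-annotated VCF
# ----------------------------------------------------------------------
def read_spliceai_vcf(
    path: str | Path, info_field: str = "SpliceAI"
) -> tuple[list[tuple[GenomicVariant, SpliceAIAnnotation]], int]:
    """Parse variants with SpliceAI INFO annotations.

    The annotation format is
    ``ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL``,
    comma-separated when a variant is annotated on several genes — one
    output record per variant x gene entry. Records with a missing INFO
    key or a malformed annotation string are skipped with a logged
    message; the skip count is returned alongside the records.
    """
    records: list[tuple[GenomicVariant, SpliceAIAnnotation]] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if info_field not in rec.info:
                logger.warning(
                    "%s:%d: no %s INFO field — record skipped",
                    rec.chrom,
                    rec.pos,
                    info_field,
                )
                skipped += 1
                continue
            raw = rec.info[info_field]
            entries = raw if isinstance(raw, tuple) else (raw,)
            for entry in entries:
                fields = str(entry).split("|")
                if len(fields) != 10:
                    logger.warning(
                        "%s:%d: malformed %s entry %r — skipped",
                        rec.chrom,
                        rec.pos,
                        info_field,
                        entry,
                    )
                    skipped += 1
                    continue
                try:
                    ann = SpliceAIAnnotation(
                        ds_ag=float(fields[2]),
                        ds_al=float(fields[3]),
                        ds_dg=float(fields[4]),
                        ds_dl=float(fields[5]),
                        dp_ag=int(fields[6]),
                        dp_al=int(fields[7]),
                        dp_dg=int(fields[8]),
                        dp_dl=int(fields[9]),
                        gene_id=fields[1],
                    )
                except ValueError as exc:
                    logger.warning(
                        "%s:%d: unparseable %s entry %r (%s) — skipped",
                        rec.chrom,
                        rec.pos,
                        info_field,
                        entry,
                        exc,
                    )
                    skipped += 1
                    continue
                alt = fields[0] or (rec.alts[0] if rec.alts else "")
                variant = GenomicVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,  # pysam reports 1-based pos
                    ref=rec.ref,
                    alt=alt,
                    gene_id=fields[1],
                )
                records.append((variant, ann))
    return records, skipped


def select_annotation(
    anns: Iterable[SpliceAIAnnotation], gene_id: str, region_class: str = "deep_intronic"
) -> SpliceAIAnnotation:
    """Pick the annotation entry for ``gene_id``; fall back to max-DS.

    Multi-gene annotations: the entry whose gene symbol matches is used;
    if none matches, the entry with the largest relevant delta score is
    returned with a warning.
    """
    from .variants import spliceai_ds

    anns = list(anns)
    if not anns:
        raise ValueError("no annotation entries supplied")
    for ann in anns:
        if ann.gene_id == gene_id:
            return ann
    best = max(anns, key=lambda a: spliceai_ds(a, region_class))
    logger.warning(
        "no annotation entry for gene %r; using max-DS entry (gene %r)",
        gene_id,
        best.gene_id,
    )
    return best


# ----------------------------------------------------------------------
# variant TSV tables
# ----------------------------------------------------------------------
def read_variant_tsv(path: str | Path) -> pd.DataFrame:
    """Read a variant table (tab-separated, '.' for null, header required)."""
    df = pd.read_csv(path, sep="\t", na_values=[NULL_TOKEN], keep_default_na=True)
    missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: variant TSV missing required columns {missing}")
    return df


def write_scored_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a scored table: tab-separated, '.' for null, header mandatory."""
    df.to_csv(path, sep="\t", index=False, na_rep=NULL_TOKEN, float_format="%.6g")


def read_scored_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NULL_TOKEN], keep_default_na=True)


# ----------------------------------------------------------------------
# gene models
# ----------------------------------------------------------------------
def read_bed12(path: str | Path) -> list[GeneModel]:
    """Gene models from BED12 (blocks expanded into exon intervals)."""
    models: list[GeneModel] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: BED12 requires 12 columns, got {len(fields)}"
                )
            chrom, chrom_start, _end, name = fields[0], int(fields[1]), fields[2], fields[3]
            strand = fields[5]
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            exons = [
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            ]
            if strand == "-":
                exons = exons[::-1]  # transcription order
            models.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    transcript_id=name,
                )
            )
    return models


def read_gff3_exons(path: str | Path) -> list[GeneModel]:
    """Gene models from a minimal GFF3 (exon features grouped by Parent).

    Only ``exon`` features are consulted; grouping uses the ``Parent``
    attribute (falling back to ``gene_id``/``ID``).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, list] = {}
    for feat in db.features_of_type("exon"):
        parent = (
            feat.attributes.get("Parent", [None])[0]
            or feat.attributes.get("gene_id", [None])[0]
            or feat.attributes.get("ID", ["unnamed"])[0]
        )
        grouped.setdefault(parent, []).append(feat)
    models = []
    for parent, feats in grouped.items():
        strand = feats[0].strand
        chrom = feats[0].seqid
        exons = sorted((f.start - 1, f.end) for f in feats)  # GFF is 1-based closed
        if strand == "-":
            exons = exons[::-1]
        models.append(
            GeneModel(
                gene_id=parent, chrom=chrom, strand=strand, exons=exons,
                transcript_id=parent,
            )
        )
    return models


# ----------------------------------------------------------------------
# landscape output
# ----------------------------------------------------------------------
REPORT_COLUMNS = [
    "region_id",
    "length",
    "area",
    "normalized_area",
    "flank_acceptor_area",
    "flank_acceptor_normalized_area",
    "flank_donor_area",
    "flank_donor_normalized_area",
    "contrast",
]


def write_region_report(landscapes: Iterable[RegionLandscape], path: str | Path) -> None:
    """Per-region landscape TSV (fixed column order, 6-decimal floats)."""
    rows = []
    for ls in landscapes:
        rows.append(
            {
                "region_id": ls.region_id,
                "length": ls.region.length,
                "area": round(ls.region.area, 6),
                "normalized_area": round(ls.region.normalized_area, 6),
                "flank_acceptor_area": round(ls.flank_acceptor.area, 6),
                "flank_acceptor_normalized_area": round(
                    ls.flank_acceptor.normalized_area, 6
                ),
                "flank_donor_area": round(ls.flank_donor.area, 6),
                "flank_donor_normalized_area": round(ls.flank_donor.normalized_area, 6),
                "contrast": round(ls.contrast, 6),
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep=NULL_TOKEN)


def read_region_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NULL_TOKEN])


def write_bedgraph(
    chrom: str,
    windows: Iterable[tuple[int, float]],
    window_len: int,
    path: str | Path,
    name: str = "normalized_sre_area",
) -> None:
    """Windowed normalized-area track in bedGraph (0-based half-open)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for start, value in windows:
            fh.write(f"{chrom}\t{start}\t{start + window_len}\t{value:.6f}\n")
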