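import numpy as np
import pytest
from hypothesis import given, strategies as st

from spliceland import (
    DictGenome,
    GeneModel,
    GenomicVariant,
    HexamerTable,
    SpliceAIAnnotation,
    deep_intronic_class,
    delta_esrseq,
    flank_abs_diff,
    score_variant,
    spliceai_ds,
)
from spliceland.hexamers import revcomp

from .conftest import brute_force_per_nt, brute_force_window_total, random_dna


# ----------------------------------------------------------------------
# DS extraction
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "ann_kwargs, region_class, expected",
    [
        # intronic: max of the gain scores
        (dict(ds_ag=0.74, ds_al=0.0, ds_dg=0.71, ds_dl=0.0), "deep_intronic", 0.74),
        (dict(ds_ag=0.93, ds_al=0.0, ds_dg=0.69, ds_dl=0.0), "deep_intronic", 0.93),
        (dict(ds_ag=0.41, ds_al=0.0, ds_dg=0.05, ds_dl=0.0), "deep_intronic", 0.41),
        (dict(ds_ag=0.1, ds_al=0.0, ds_dg=0.3, ds_dl=0.0), "near_splice_intronic", 0.3),
        # exonic: max of the loss scores, even when gains are larger
        (dict(ds_ag=0.9, ds_al=0.1, ds_dg=0.9, ds_dl=0.05), "exonic", 0.1),
    ],
)
def test_spliceai_ds_gain_for_intronic_loss_for_exonic(ann_kwargs, region_class, expected):
    ann = SpliceAIAnnotation(**ann_kwargs)
    assert spliceai_ds(ann, region_class) == pytest.approx(expected)


def test_spliceai_ds_never_exceeds_raw_max_and_is_idempotent():
    ann = SpliceAIAnnotation(ds_ag=0.3, ds_al=0.6, ds_dg=0.2, ds_dl=0.1)
    for rc in ("deep_intronic", "exonic"):
        ds = spliceai_ds(ann, rc)
        assert ds <= max(0.3, 0.6, 0.2, 0.1)
        assert spliceai_ds(ann, rc) == ds


def test_annotation_validation():
    with pytest.raises(ValueError, match="outside"):
        SpliceAIAnnotation(ds_ag=1.2, ds_al=0, ds_dg=0, ds_dl=0)
    with pytest.raises(ValueError, match="window"):
        SpliceAIAnnotation(ds_ag=0.1, ds_al=0, ds_dg=0, ds_dl=0, dp_ag=6000)


# ----------------------------------------------------------------------
# ΔESRseq
# ----------------------------------------------------------------------
TOY5 = HexamerTable.filled(
    {"ACGTAC": 0.8, "CGTACG": -0.5, "GTACGT": 0.25, "TACGTT": -0.9, "ACGTTC": 0.6},
    source_label="toy5",
)
CONTIG = "AAACGTACGTACGGTACGTACGTACAAAAA"  # SNV target G at 1-based 14


def test_delta_esrseq_identity_variant_is_zero():
    genome = DictGenome({"c": CONTIG})
    v = GenomicVariant(chrom="c", pos=14, ref="G", alt="G")
    assert delta_esrseq(v, genome, TOY5) == 0.0


def test_delta_esrseq_constant_table_is_zero(constant_table):
    genome = DictGenome({"c": CONTIG})
    v = GenomicVariant(chrom="c", pos=14, ref="G", alt="T")
    # both 11-mers contain 6 hexamers scoring c: 6c - 6c = 0
    assert delta_esrseq(v, genome, constant_table) == pytest.approx(0.0)


def test_delta_esrseq_matches_frozen_enumeration():
    # Independently enumerated: WT 11-mer GTACGGTACGT (total 0.25),
    # variant 11-mer GTACGTTACGT (total -0.65) under TOY5.
    genome = DictGenome({"c": CONTIG})
    v = GenomicVariant(chrom="c", pos=14, ref="G", alt="T")
    assert delta_esrseq(v, genome, TOY5) == pytest.approx(-0.9)


def test_delta_esrseq_ref_mismatch_rejected():
    genome = DictGenome({"c": CONTIG})
    v = GenomicVariant(chrom="c", pos=14, ref="A", alt="T")
    with pytest.raises(ValueError, match="mismatch"):
        delta_esrseq(v, genome, TOY5)


def test_delta_esrseq_indel_extension(random_table, caplog):
    import logging

    rng = np.random.default_rng(5)
    seq = random_dna(rng, 60)
    genome = DictGenome({"c": seq})
    v = GenomicVariant(chrom="c", pos=21, ref=seq[20:24], alt=seq[20])  # 3-nt deletion
    with caplog.at_level(logging.INFO, logger="spliceland.variants"):
        d = delta_esrseq(v, genome, random_table)
    wt = seq[15:20] + seq[20:24] + seq[24:29]
    var = seq[15:20] + seq[20] + seq[24:29]
    expected = brute_force_window_total(var, random_table) - brute_force_window_total(
        wt, random_table
    )
    assert d == pytest.approx(expected)
    assert any("extension" in r.message for r in caplog.records)


@given(pos=st.integers(min_value=6, max_value=55), alt=st.sampled_from("ACGT"))
def test_delta_esrseq_antisymmetric_under_allele_swap(random_table, pos, alt):
    rng = np.random.default_rng(99)
    seq = random_dna(rng, 60)
    ref = seq[pos - 1]
    if ref == alt:
        return
    genome = DictGenome({"c": seq})
    fwd = GenomicVariant(chrom="c", pos=pos, ref=ref, alt=alt)
    mutated = seq[: pos - 1] + alt + seq[pos:]
    rev = GenomicVariant(chrom="c", pos=pos, ref=alt, alt=ref)
    d_fwd = delta_esrseq(fwd, genome, random_table)
    d_rev = delta_esrseq(rev, DictGenome({"c": mutated}), random_table)
    assert d_fwd == pytest.approx(-d_rev)


def test_delta_esrseq_minus_strand_scores_sense_sequence(random_table):
    rng = np.random.default_rng(7)
    seq = random_dna(rng, 40)
    genome = DictGenome({"c": seq})
    pos = 20
    ref = seq[pos - 1]
    alt = "A" if ref != "A" else "C"
    minus = GenomicVariant(chrom="c", pos=pos, ref=ref, alt=alt, strand="-")
    # equivalent plus-strand construction on the reverse-complement contig
    flipped = DictGenome({"c": revcomp(seq)})
    pos_rc = len(seq) - pos + 1
    plus = GenomicVariant(
        chrom="c", pos=pos_rc, ref=revcomp(ref), alt=revcomp(alt), strand="+"
    )
    assert delta_esrseq(minus, genome, random_table) == pytest.approx(
        delta_esrseq(plus, flipped, random_table)
    )


# ----------------------------------------------------------------------
# flank absolute difference
# ----------------------------------------------------------------------
def _rotations(hexamer):
    doubled = hexamer + hexamer
    return {doubled[i : i + 6] for i in range(6)}


PLANTED = HexamerTable.filled(
    {**{h: 0.4 for h in _rotations("AAACCC")}, **{h: -0.4 for h in _rotations("GGGTTT")}},
    source_label="planted-flanks",
)
# upstream repeat covers [0, 120); variant base = first downstream base
FLANK_CONTIG = "AAACCC" * 20 + "GGGTTT" * 20


def test_flank_abs_diff_identical_flanks_is_zero(random_table):
    # paste the upstream window (plus its 5-nt contexts) into the
    # downstream window location: the two flanks become byte-identical
    rng = np.random.default_rng(3)
    seq = list(random_dna(rng, 400))
    p0 = 199  # 0-based variant position; q0 = 200
    seq[200:310] = seq[p0 - 110 : p0]
    seq = "".join(seq)
    genome = DictGenome({"c": seq})
    ref = seq[p0]
    v = GenomicVariant(chrom="c", pos=200, ref=ref, alt="A" if ref != "A" else "T")
    assert flank_abs_diff(v, genome, random_table) == pytest.approx(0.0, abs=1e-12)


def test_flank_abs_diff_planted_means_give_expected_gap():
    genome = DictGenome({"c": FLANK_CONTIG})
    v = GenomicVariant(chrom="c", pos=121, ref="G", alt="A")
    val = flank_abs_diff(v, genome, PLANTED)
    # windows sit entirely inside the pure repeats: exactly |0.4 - (-0.4)|
    assert val == pytest.approx(0.8)


def test_flank_abs_diff_matches_independent_recomputation(random_table):
    rng = np.random.default_rng(31)
    seq = random_dna(rng, 400)
    genome = DictGenome({"c": seq})
    v = GenomicVariant(chrom="c", pos=200, ref=seq[199], alt="A" if seq[199] != "A" else "C")
    got = flank_abs_diff(v, genome, random_table)
    p0, q0 = 199, 200
    up = brute_force_per_nt(
        seq[p0 - 105 : p0 - 5], random_table,
        left=seq[p0 - 110 : p0 - 105], right=seq[p0 - 5 : p0],
    )
    down = brute_force_per_nt(
        seq[q0 + 5 : q0 + 105], random_table,
        left=seq[q0 : q0 + 5], right=seq[q0 + 105 : q0 + 110],
    )
    assert got == pytest.approx(abs(up.mean() - down.mean()))


def test_flank_windows_exclude_variant_affected_hexamers(random_table):
    # no hexamer overlapping the variant base contributes to either flank
    # window: substituting the variant base leaves the value unchanged
    rng = np.random.default_rng(13)
    seq = random_dna(rng, 400)
    v_pos = 200
    i = v_pos - 1
    values = []
    for base in "ACGT":
        mutated = seq[:i] + base + seq[i + 1 :]
        v = GenomicVariant(
            chrom="c", pos=v_pos, ref=base, alt="T" if base != "T" else "G"
        )
        values.append(flank_abs_diff(v, DictGenome({"c": mutated}), random_table))
    assert all(v == pytest.approx(values[0]) for v in values)


def test_flank_abs_diff_swap_and_strand_invariance(random_table):
    rng = np.random.default_rng(17)
    seq = random_dna(rng, 400)
    genome = DictGenome({"c": seq})
    ref = seq[199]
    alt = "A" if ref != "A" else "C"
    plus = GenomicVariant(chrom="c", pos=200, ref=ref, alt=alt, strand="+")
    val_plus = flank_abs_diff(plus, genome, random_table)
    assert val_plus >= 0
    # reverse-complement the locus and flip strand: value unchanged
    flipped = DictGenome({"c": revcomp(seq)})
    minus_equiv = GenomicVariant(
        chrom="c", pos=len(seq) - 199, ref=revcomp(ref), alt=revcomp(alt), strand="-"
    )
    # scoring the '-' variant on the flipped contig re-reads the original
    # sense sequence, with upstream/downstream windows swapped
    assert flank_abs_diff(minus_equiv, flipped, random_table) == pytest.approx(val_plus)


def test_flank_abs_diff_insufficient_sequence_rejected(random_table):
    genome = DictGenome({"c": "ACGT" * 30})
    v = GenomicVariant(chrom="c", pos=50, ref="C", alt="T")
    with pytest.raises(ValueError, match="require span"):
        flank_abs_diff(v, genome, random_table)


# ----------------------------------------------------------------------
# deep-intronic classification
# ----------------------------------------------------------------------
MODEL = GeneModel(
    gene_id="G", chrom="c", strand="+", exons=[(100, 200), (300, 400)]
)


@pytest.mark.parametrize(
    "pos0, expected_class, expected_dist",
    [
        (220, "deep_intronic", 21),  # 21 nt past the donor junction
        (219, "near_splice_intronic", 20),  # exactly 20 nt: not deep
        (200, "near_splice_intronic", 1),  # first intronic base
        (279, "deep_intronic", 21),  # 21 nt before the acceptor
        (150, "exonic", 50),
        (100, "exonic", 1),  # first exon base
    ],
)
def test_deep_intronic_distance_rule(pos0, expected_class, expected_dist):
    v = GenomicVariant(chrom="c", pos=pos0 + 1, ref="A", alt="T")
    cls, dist = deep_intronic_class(v, MODEL)
    assert cls == expected_class
    assert dist == expected_dist


def test_variant_outside_transcript_rejected():
    v = GenomicVariant(chrom="c", pos=50, ref="A", alt="T")
    with pytest.raises(ValueError, match="outside transcript"):
        deep_intronic_class(v, MODEL)


# ----------------------------------------------------------------------
# bundling
# ----------------------------------------------------------------------
def test_score_variant_composes_components(random_table):
    rng = np.random.default_rng(23)
    seq = random_dna(rng, 400)
    genome = DictGenome({"c": seq})
    ref = seq[199]
    v = GenomicVariant(chrom="c", pos=200, ref=ref, alt="A" if ref != "A" else "C")
    ann = SpliceAIAnnotation(ds_ag=0.41, ds_al=0.0, ds_dg=0.05, ds_dl=0.0, dp_ag=-4)
    ss = score_variant(v, ann, genome, random_table, region_class="deep_intronic")
    assert ss.ds == pytest.approx(0.41)
    assert ss.ds_positions["dp_ag"] == -4
    assert ss.delta_esrseq == pytest.approx(delta_esrseq(v, genome, random_table))
    assert ss.abs_diff == pytest.approx(flank_abs_diff(v, genome, random_table))


def test_score_variant_without_annotation_gives_null_ds(random_table):
    rng = np.random.default_rng(29)
    seq = random_dna(rng, 400)
    genome = DictGenome({"c": seq})
    ref = seq[199]
    v = GenomicVariant(chrom="c", pos=200, ref=ref, alt="A" if ref != "A" else "C")
    ss = score_variant(v, None, genome, random_table)
    assert ss.ds is None
    assert ss.delta_esrseq is not None and ss.abs_diff is not None
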