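"""Deterministic synthetic fixtures: tables, genes and variant benchmarks.

Every generator is a pure function of its spec (same spec, byte-identical
output) and plants known structure so downstream scoring, landscape and
pipeline logic can be tested without downloading an empirical hexamer
table or real gene sequences:

* :func:`gen_hexamer_table` — a complete 4096-entry table with designated
  enhancer/silencer/neutral hexamer classes drawn from normal
  distributions, class membership recorded for oracles.
* :func:`gen_gene_fixture` — a genome where exons are built from
  enhancer-class hexamers, introns from silencer-class hexamers, plus one
  pseudoexon-like intronic island of intermediate enhancer bias; the
  sidecar records every planted region.
* :func:`gen_variant_dataset` — a labeled score table emulating the
  composition of a curated deep-intronic benchmark (133 splice-altering
  variants split 117 cryptic-site / 16 SRE mechanism, 100 without
  effect), with a planted DS decision boundary and optional label noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hexamers import HexamerTable, all_hexamers
from .io import DictGenome, write_fasta
from .landscape import GeneModel

__all__ = [
    "TableSpec",
    "GeneFixtureSpec",
    "VariantDatasetSpec",
    "SyntheticHexamerTable",
    "GeneFixture",
    "gen_hexamer_table",
    "gen_gene_fixture",
    "gen_variant_dataset",
]


# ----------------------------------------------------------------------
# hexamer tables
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class TableSpec:
    """Parameters of a synthetic hexamer score table.

    About a quarter of hexamers is designated enhancer-class (scores ~
    N(mean_enhancer, sd)), a disjoint quarter silencer-class, and the
    rest neutral (score 0 when ``sd_neutral`` is 0). Classes are closed
    under cyclic rotation (whole rotation orbits are assigned to one
    class), so a tandem repeat of a class hexamer scores in-class at
    every sliding window — this is what lets gene fixtures plant region
    biases that hold by construction rather than in expectation. Orbit
    granularity means class sizes match the requested fractions to
    within 5 hexamers.
    """

    seed: int = 0
    mean_enhancer: float = 0.3
    mean_silencer: float = -0.3
    sd: float = 0.1
    frac_enhancer: float = 0.25
    frac_silencer: float = 0.25
    sd_neutral: float = 0.0

    def __post_init__(self) -> None:
        if self.frac_enhancer < 0 or self.frac_silencer < 0:
            raise ValueError("class fractions must be non-negative")
        if self.frac_enhancer + self.frac_silencer > 1.0:
            raise ValueError(
                "enhancer and silencer classes overlap: fractions sum to "
                f"{self.frac_enhancer + self.frac_silencer} > 1"
            )


@dataclass
class SyntheticHexamerTable:
    """A generated table plus its planted class membership."""

    table: HexamerTable
    classes: dict[str, str]  # hexamer -> {enhancer, silencer, neutral}
    spec: TableSpec

    def hexamers_of(self, cls: str) -> list[str]:
        return [h for h, c in self.classes.items() if c == cls]


def _rotation_orbits() -> list[tuple[str, ...]]:
    """Partition the 4096 hexamers into cyclic-rotation orbits."""
    seen: set[str] = set()
    orbits: list[tuple[str, ...]] = []
    for h in all_hexamers():
        if h in seen:
            continue
        orbit = sorted({h[i:] + h[:i] for i in range(6)})
        seen.update(orbit)
        orbits.append(tuple(orbit))
    return orbits


def gen_hexamer_table(spec: TableSpec) -> SyntheticHexamerTable:
    rng = np.random.default_rng(spec.seed)
    n = 4096
    n_enh = int(round(spec.frac_enhancer * n))
    n_sil = int(round(spec.frac_silencer * n))
    orbits = _rotation_orbits()
    order = rng.permutation(len(orbits))

    classes: dict[str, str] = {}
    assigned_enh = assigned_sil = 0
    for idx in order:
        orbit = orbits[idx]
        if assigned_enh < n_enh:
            cls = "enhancer"
            assigned_enh += len(orbit)
        elif assigned_sil < n_sil:
            cls = "silencer"
            assigned_sil += len(orbit)
        else:
            cls = "neutral"
        for h in orbit:
            classes[h] = cls

    scores: dict[str, float] = {}
    for h in all_hexamers():
        cls = classes[h]
        if cls == "enhancer":
            scores[h] = float(rng.normal(spec.mean_enhancer, spec.sd))
        elif cls == "silencer":
            scores[h] = float(rng.normal(spec.mean_silencer, spec.sd))
        else:
            scores[h] = (
                float(rng.normal(0.0, spec.sd_neutral)) if spec.sd_neutral > 0 else 0.0
            )
    table = HexamerTable(scores, source_label=f"synthetic(seed={spec.seed})")
    return SyntheticHexamerTable(table=table, classes=classes, spec=spec)


# ----------------------------------------------------------------------
# gene fixtures with planted landscapes
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GeneFixtureSpec:
    """A synthetic gene with planted SRE structure.

    Exons are concatenations of enhancer-class hexamers, introns of
    silencer-class hexamers; one pseudoexon-like island of intermediate
    bias (a hexamer mix with ``island_enhancer_frac`` enhancers) is
    planted in the middle of intron ``island_intron`` (1-based). Region
    lengths need not be multiples of 6 (the final hexamer is truncated).
    """

    seed: int = 0
    table: TableSpec = field(default_factory=TableSpec)
    exon_lens: tuple[int, ...] = (120, 150, 120)
    intron_len: int = 1200
    outer_flank_len: int = 400
    island_len: int = 144  # 6 runs of 24 nt: exact 2/3 enhancer mix
    island_intron: int = 1
    island_enhancer_frac: float = 2.0 / 3.0
    strand: str = "+"
    chrom: str = "chrSim"
    gene_id: str = "SIMGENE"

    def __post_init__(self) -> None:
        if not (0.0 <= self.island_enhancer_frac <= 1.0):
            raise ValueError("island_enhancer_frac must be in [0, 1]")
        if not (1 <= self.island_intron <= len(self.exon_lens) - 1):
            raise ValueError(
                f"island_intron must name one of the {len(self.exon_lens) - 1} introns"
            )
        if self.intron_len < self.island_len + 2 * 210:
            raise ValueError(
                "introns must leave >=210 nt on each side of the island so "
                "island flanks are purely intronic"
            )


@dataclass
class GeneFixture:
    """Generated genome + model + paired table + planted-truth sidecar."""

    genome: DictGenome
    model: GeneModel
    table: SyntheticHexamerTable
    truth: dict
    spec: GeneFixtureSpec

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome.fa, gene.bed (BED12), table.tsv and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "bed": outdir / "gene.bed",
            "table": outdir / "table.tsv",
            "truth": outdir / "truth.json",
        }
        chrom = self.model.chrom
        write_fasta({chrom: self.genome.fetch(chrom, 0, self.genome.length(chrom))},
                    paths["fasta"])
        exons = sorted(self.model.exons)
        start, end = exons[0][0], exons[-1][1]
        sizes = ",".join(str(e - s) for s, e in exons)
        offsets = ",".join(str(s - start) for s, _ in exons)
        with paths["bed"].open("w") as fh:
            fh.write(
                "\t".join(
                    [
                        chrom,
                        str(start),
                        str(end),
                        self.model.gene_id,
                        "0",
                        self.model.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )
        self.table.table.to_tsv(paths["table"])
        with paths["truth"].open("w") as fh:
            json.dump(self.truth, fh, indent=2)
        return paths


RUN_LEN_HEXAMERS = 4  # each sampled hexamer is tandem-repeated 4x (24 nt)


def _sample_region(rng: np.random.Generator, pool: list[str], length: int) -> str:
    # tandem runs: with rotation-closed classes every window inside a run
    # scores in-class, so the planted bias survives sliding-window scoring
    run_nt = 6 * RUN_LEN_HEXAMERS
    n_runs = -(-length // run_nt)  # ceil
    picks = rng.choice(len(pool), size=n_runs, replace=True)
    return "".join(pool[i] * RUN_LEN_HEXAMERS for i in picks)[:length]


def _sample_island(
    rng: np.random.Generator,
    enh_pool: list[str],
    sil_pool: list[str],
    length: int,
    enh_frac: float,
) -> str:
    # exact class counts over runs (not coin flips) so the island's
    # intermediate bias — and hence the exon > island > intron ordering —
    # is guaranteed by construction, not just in expectation
    run_nt = 6 * RUN_LEN_HEXAMERS
    n_runs = -(-length // run_nt)
    n_enh = int(round(enh_frac * n_runs))
    picks = [enh_pool[rng.integers(len(enh_pool))] for _ in range(n_enh)]
    picks += [sil_pool[rng.integers(len(sil_pool))] for _ in range(n_runs - n_enh)]
    order = rng.permutation(n_runs)
    return "".join(picks[i] * RUN_LEN_HEXAMERS for i in order)[:length]


def gen_gene_fixture(spec: GeneFixtureSpec) -> GeneFixture:
    synth = gen_hexamer_table(spec.table)
    enh = synth.hexamers_of("enhancer")
    sil = synth.hexamers_of("silencer")
    if not enh or not sil:
        raise ValueError(
            "gene fixtures need non-empty enhancer and silencer hexamer classes"
        )
    rng = np.random.default_rng(spec.seed)

    pieces: list[str] = []
    cursor = 0
    exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    island: tuple[int, int] | None = None

    def _append(seq: str) -> tuple[int, int]:
        nonlocal cursor
        pieces.append(seq)
        iv = (cursor, cursor + len(seq))
        cursor += len(seq)
        return iv

    _append(_sample_region(rng, sil, spec.outer_flank_len))
    for i, exon_len in enumerate(spec.exon_lens):
        exons.append(_append(_sample_region(rng, enh, exon_len)))
        if i < len(spec.exon_lens) - 1:
            intron_index = i + 1
            if intron_index == spec.island_intron:
                pad = (spec.intron_len - spec.island_len) // 2
                intron_start = cursor
                _append(_sample_region(rng, sil, pad))
                island = _append(
                    _sample_island(rng, enh, sil, spec.island_len,
                                   spec.island_enhancer_frac)
                )
                _append(
                    _sample_region(rng, sil,
                                   spec.intron_len - pad - spec.island_len)
                )
                introns.append((intron_start, cursor))
            else:
                introns.append(_append(_sample_region(rng, sil, spec.intron_len)))
    _append(_sample_region(rng, sil, spec.outer_flank_len))

    sequence = "".join(pieces)
    genome = DictGenome({spec.chrom: sequence})
    model_exons = exons if spec.strand == "+" else exons[::-1]
    model = GeneModel(
        gene_id=spec.gene_id,
        chrom=spec.chrom,
        strand=spec.strand,
        exons=model_exons,
        transcript_id=spec.gene_id + ".1",
    )
    assert island is not None
    truth = {
        "chrom": spec.chrom,
        "strand": spec.strand,
        "exons": [list(iv) for iv in exons],
        "introns": [list(iv) for iv in introns],
        "island": list(island),
        "expected_sign": {"exon": "+", "island": "+", "intron": "-"},
        "class_means": {
            "enhancer": spec.table.mean_enhancer,
            "silencer": spec.table.mean_silencer,
            "island": spec.island_enhancer_frac * spec.table.mean_enhancer
            + (1 - spec.island_enhancer_frac) * spec.table.mean_silencer,
        },
        "spec": {
            "seed": spec.seed,
            "table_seed": spec.table.seed,
            "exon_lens": list(spec.exon_lens),
            "intron_len": spec.intron_len,
            "island_len": spec.island_len,
            "island_intron": spec.island_intron,
            "island_enhancer_frac": spec.island_enhancer_frac,
        },
    }
    return GeneFixture(genome=genome, model=model, table=synth, truth=truth, spec=spec)


# ----------------------------------------------------------------------
# labeled variant datasets with planted decision structure
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class VariantDatasetSpec:
    """Composition and score distributions of a synthetic benchmark.

    Defaults mirror the curated literature benchmark the framework was
    evaluated on: 133 splice-altering variants (117 via cryptic splice
    sites, 16 via SRE alteration) and 100 variants without effect.
    Cryptic-site positives draw DS above ``ds_boundary`` (Beta-shaped,
    dense near the boundary); SRE positives draw DS below the boundary
    with ΔESRseq >= ``t_esr`` and abs-diff >= ``t_abs``; negatives stay
    below all three cut-offs. ``noise_rate`` flips each label
    independently.
    """

    seed: int = 0
    n_cryptic: int = 117
    n_sre: int = 16
    n_neg: int = 100
    ds_boundary: float = 0.05
    t_esr: float = 0.63
    t_abs: float = 0.51
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.ds_boundary < 1.0):
            raise ValueError("ds_boundary must lie strictly inside (0, 1)")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate must be in [0, 1]")
        if min(self.n_cryptic, self.n_sre, self.n_neg) < 0:
            raise ValueError("cohort sizes must be non-negative")


def _truncated_below(rng: np.random.Generator, draw, bound: float, n: int) -> np.ndarray:
    """n draws from ``draw`` rejected until strictly below ``bound``."""
    out = np.empty(n)
    for i in range(n):
        for _ in range(1000):
            v = draw(rng)
            if v < bound:
                out[i] = v
                break
        else:
            raise ValueError("distribution bounds infeasible: rejection cap hit")
    return out


def gen_variant_dataset(spec: VariantDatasetSpec) -> pd.DataFrame:
    """Labeled score table with a planted decision structure.

    Columns: ``variant_id``, ``mechanism`` (cryptic_site / sre / none —
    the generating-truth sidecar), ``true_label`` (pre-noise),
    ``label`` (post-noise, 1 = splice-altering), ``ds``,
    ``delta_esrseq``, ``abs_diff``. Row order is a seeded shuffle.
    """
    rng = np.random.default_rng(spec.seed)
    b = spec.ds_boundary
    rows = []

    ds_cryptic = b + (1.0 - b) * rng.beta(1.2, 3.0, size=spec.n_cryptic)
    esr_cryptic = rng.normal(0.0, 0.4, size=spec.n_cryptic)
    abs_cryptic = rng.exponential(0.5, size=spec.n_cryptic)
    for i in range(spec.n_cryptic):
        rows.append(("cryptic_site", 1, ds_cryptic[i], esr_cryptic[i], abs_cryptic[i]))

    # sub-boundary DS follows the same shape for SRE positives and
    # negatives: below the planted boundary DS carries no signal, so the
    # boundary itself is the identifiable decision point
    ds_sre = b * rng.beta(1.0, 3.0, size=spec.n_sre)
    esr_sre = spec.t_esr + rng.exponential(0.3, size=spec.n_sre)
    abs_sre = spec.t_abs + rng.exponential(0.4, size=spec.n_sre)
    for i in range(spec.n_sre):
        rows.append(("sre", 1, ds_sre[i], esr_sre[i], abs_sre[i]))

    ds_neg = b * rng.beta(1.0, 3.0, size=spec.n_neg)
    esr_neg = _truncated_below(
        rng, lambda r: r.normal(0.0, 0.25), spec.t_esr, spec.n_neg
    )
    abs_neg = _truncated_below(
        rng, lambda r: r.exponential(0.15), spec.t_abs, spec.n_neg
    )
    for i in range(spec.n_neg):
        rows.append(("none", 0, ds_neg[i], esr_neg[i], abs_neg[i]))

    df = pd.DataFrame(
        rows, columns=["mechanism", "true_label", "ds", "delta_esrseq", "abs_diff"]
    )
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    flip = rng.random(len(df)) < spec.noise_rate
    df["label"] = np.where(flip, 1 - df["true_label"], df["true_label"]).astype(int)
    df.insert(0, "variant_id", [f"var{i + 1:04d}" for i in range(len(df))])
    return df[
        ["variant_id", "mechanism", "true_label", "label", "ds", "delta_esrseq", "abs_diff"]
    ]
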