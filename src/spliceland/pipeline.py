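"""Sequential decision rules for prioritizing spliceogenic variants.

Three nested pipelines, applied per variant:

1. ``spliceai_only`` — positive iff DS >= t_ds (a cryptic splice site is
   created/enhanced near the variant).
2. ``spliceai_esrseq`` — additionally, variants that fail the DS test
   are positive iff ΔESRseq >= t_esr (a splicing regulatory element is
   strengthened).
3. ``spliceai_esrseq_absdiff`` — as 2, but the SRE branch also requires
   the flank abs-difference >= t_abs (the variant must sit at an
   asymmetric, exonizable SRE landscape).

Default cut-offs (0.05, 0.63, 0.51) are the benchmark-optimized values
of the framework. All comparisons are inclusive (>=). The sequential
semantics mean a variant passing the DS rule never consults the SRE
scores, so a missing ΔESRseq is not an error for such variants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .variants import VariantScoreSet

__all__ = [
    "PipelineThresholds",
    "PredictionRecord",
    "ClassificationError",
    "classify",
    "batch_classify",
    "BatchResult",
    "MODE_NAMES",
]

MODE_NAMES = {
    1: "spliceai_only",
    2: "spliceai_esrseq",
    3: "spliceai_esrseq_absdiff",
}
_MODE_NUMBERS = {v: k for k, v in MODE_NAMES.items()}

CRYPTIC_SITE_RULE = "cryptic_site_rule"
SRE_RULE = "sre_rule"
NO_RULE = "none"


class ClassificationError(ValueError):
    """A variant could not be classified (required score missing)."""


@dataclass(frozen=True)
class PipelineThresholds:
    """Decision cut-offs and pipeline mode.

    ``mode`` may be given as 1/2/3 or by name; it determines which
    thresholds are consulted.
    """

    t_ds: float = 0.05
    t_esr: float = 0.63
    t_abs: float = 0.51
    mode: str = "spliceai_esrseq_absdiff"

    def __post_init__(self) -> None:
        if isinstance(self.mode, int):
            object.__setattr__(self, "mode", MODE_NAMES[self.mode])
        if self.mode not in _MODE_NUMBERS:
            raise ValueError(
                f"mode must be one of {sorted(_MODE_NUMBERS)} or 1/2/3, "
                f"got {self.mode!r}"
            )
        if not (0.0 <= self.t_ds <= 1.0):
            raise ValueError(f"t_ds={self.t_ds} outside [0, 1]")

    @property
    def mode_number(self) -> int:
        return _MODE_NUMBERS[self.mode]


@dataclass(frozen=True)
class PredictionRecord:
    """Outcome of classifying one variant."""

    predicted: str  # "positive" / "negative"
    rule_fired: str  # cryptic_site_rule / sre_rule / none
    scores: VariantScoreSet
    variant_id: str = ""

    @property
    def is_positive(self) -> bool:
        return self.predicted == "positive"


def classify(
    scores: VariantScoreSet,
    thresholds: PipelineThresholds = PipelineThresholds(),
    variant_id: str = "",
) -> PredictionRecord:
    """Apply the sequential pipeline to one variant's score set."""
    th = thresholds
    if scores.ds is None:
        raise ClassificationError(
            f"variant {variant_id or '<unnamed>'}: DS missing — "
            "unclassifiable without a splice-site delta score"
        )
    if scores.ds >= th.t_ds:
        return PredictionRecord("positive", CRYPTIC_SITE_RULE, scores, variant_id)
    if th.mode == "spliceai_only":
        return PredictionRecord("negative", NO_RULE, scores, variant_id)

    if scores.delta_esrseq is None:
        raise ClassificationError(
            f"variant {variant_id or '<unnamed>'}: ΔESRseq missing but "
            f"required by mode {th.mode!r}"
        )
    sre_hit = scores.delta_esrseq >= th.t_esr
    if th.mode == "spliceai_esrseq_absdiff":
        if scores.abs_diff is None:
            raise ClassificationError(
                f"variant {variant_id or '<unnamed>'}: flank abs-difference "
                f"missing but required by mode {th.mode!r}"
            )
        sre_hit = sre_hit and scores.abs_diff >= th.t_abs
    if sre_hit:
        return PredictionRecord("positive", SRE_RULE, scores, variant_id)
    return PredictionRecord("negative", NO_RULE, scores, variant_id)


@dataclass
class BatchResult:
    """Per-variant predictions plus summary counts for one batch run."""

    records: list[PredictionRecord]
    failures: list[tuple[str, str]]  # (variant_id, reason)
    counts: Counter

    @property
    def n_positive(self) -> int:
        return sum(r.is_positive for r in self.records)


def _scores_from_row(row: pd.Series) -> VariantScoreSet:
    def _val(col: str) -> Optional[float]:
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col])

    return VariantScoreSet(
        ds=_val("ds"), delta_esrseq=_val("delta_esrseq"), abs_diff=_val("abs_diff")
    )


def batch_classify(
    table: pd.DataFrame | Iterable[VariantScoreSet],
    thresholds: PipelineThresholds = PipelineThresholds(),
) -> BatchResult:
    """Classify every row of a scored table; failures are collected.

    ``table`` is either a DataFrame with columns ``ds``,
    ``delta_esrseq``, ``abs_diff`` (and optionally ``variant_id``) or an
    iterable of :class:`VariantScoreSet`. Output ordering matches input;
    per-row classification errors are recorded and the run continues.
    """
    items: list[tuple[str, object]]
    if isinstance(table, pd.DataFrame):
        items = [
            (
                str(row["variant_id"]) if "variant_id" in table.columns else str(i),
                row,
            )
            for i, (_, row) in enumerate(table.iterrows())
        ]
    else:
        items = [(str(i), s) for i, s in enumerate(table)]

    records: list[PredictionRecord] = []
    failures: list[tuple[str, str]] = []
    counts: Counter = Counter()
    for variant_id, item in items:
        try:
            scores = item if isinstance(item, VariantScoreSet) else _scores_from_row(item)
            rec = classify(scores, thresholds, variant_id=variant_id)
        except (ClassificationError, ValueError) as exc:
            failures.append((variant_id, str(exc)))
            counts["failed"] += 1
            continue
        records.append(rec)
        counts[rec.rule_fired if rec.is_positive else "negative"] += 1
    return BatchResult(records=records, failures=failures, counts=counts)
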