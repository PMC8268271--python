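"""Hexamer score tables.

A hexamer table maps every 6-mer of DNA to a real-valued splicing
regulatory element (SRE) score: positive scores mark enhancer-like
hexamers (ESE/ISE), negative scores silencer-like ones (ESS/ISS).
Empirically derived tables of this kind (one score per 6-mer, 4096 rows)
are the substrate for all landscape and variant scoring in this package;
a synthetic generator lives in :mod:`spliceland.simulate` so nothing has
to be downloaded to run or test the framework.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "HexamerTable",
    "HexamerKeyError",
    "N_HEXAMERS",
    "all_hexamers",
    "revcomp",
]

N_HEXAMERS = 4096
_HEXAMER_RE = re.compile(r"^[ACGT]{6}$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (uppercase)."""
    return seq.translate(_COMPLEMENT)[::-1]


def all_hexamers() -> list[str]:
    """All 4096 DNA 6-mers in lexicographic order."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=6)]


class HexamerKeyError(KeyError):
    """Lookup of a hexamer that the table cannot score.

    Raised for ambiguity codes (N) and, on sparse "toy" tables, for
    hexamers absent from the table. Never silently scored as zero.
    """


@dataclass
class HexamerTable:
    """A 6-mer -> SRE score map.

    Parameters
    ----------
    scores
        Mapping from uppercase 6-letter A/C/G/T strings to scores.
        A *complete* table has all 4096 keys; sparse tables are allowed
        (toy mode) but looking up a missing hexamer raises
        :class:`HexamerKeyError`.
    source_label
        Free-text provenance of the table.
    """

    scores: dict[str, float]
    source_label: str = "unnamed"

    def __post_init__(self) -> None:
        for k in self.scores:
            if not _HEXAMER_RE.match(k):
                raise ValueError(
                    f"invalid hexamer key {k!r}: must match [ACGT]{{6}}"
                )

    @property
    def complete(self) -> bool:
        return len(self.scores) == N_HEXAMERS

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, hexamer: str) -> bool:
        return hexamer in self.scores

    def __getitem__(self, hexamer: str) -> float:
        try:
            return self.scores[hexamer]
        except KeyError:
            if not _HEXAMER_RE.match(hexamer):
                raise HexamerKeyError(
                    f"cannot score {hexamer!r}: not an unambiguous "
                    "[ACGT]{6} hexamer"
                ) from None
            raise HexamerKeyError(
                f"hexamer {hexamer!r} absent from table "
                f"{self.source_label!r} ({len(self.scores)} entries)"
            ) from None

    def get(self, hexamer: str, default: float | None = None) -> float | None:
        return self.scores.get(hexamer, default)

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def constant(cls, value: float, source_label: str = "constant") -> "HexamerTable":
        """Complete table scoring every hexamer ``value``."""
        return cls({h: value for h in all_hexamers()}, source_label)

    @classmethod
    def filled(
        cls,
        entries: Mapping[str, float],
        fill: float = 0.0,
        source_label: str = "filled",
    ) -> "HexamerTable":
        """Complete table from a few entries, all other hexamers = ``fill``."""
        scores = {h: fill for h in all_hexamers()}
        scores.update({k.upper(): float(v) for k, v in entries.items()})
        return cls(scores, source_label)

    # ------------------------------------------------------------------
    # TSV I/O: 2 columns `hexamer<TAB>score`, header optional
    # ------------------------------------------------------------------
    @classmethod
    def from_tsv(
        cls, path: str | Path, mode: str = "complete", source_label: str | None = None
    ) -> "HexamerTable":
        """Load a table from a two-column TSV.

        ``mode="complete"`` requires all 4096 hexamers; ``mode="toy"``
        permits sparse tables (missing hexamers then error on lookup).
        """
        path = Path(path)
        scores: dict[str, float] = {}
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, "
                        f"got {len(parts)}"
                    )
                hexamer, raw = parts
                hexamer = hexamer.upper()
                if lineno == 1 and not _HEXAMER_RE.match(hexamer):
                    continue  # header row
                if not _HEXAMER_RE.match(hexamer):
                    raise ValueError(f"{path}:{lineno}: bad hexamer {hexamer!r}")
                if hexamer in scores:
                    raise ValueError(f"{path}:{lineno}: duplicate hexamer {hexamer}")
                scores[hexamer] = float(raw)
        if mode == "complete" and len(scores) != N_HEXAMERS:
            raise ValueError(
                f"{path}: complete table requires {N_HEXAMERS} hexamers, "
                f"found {len(scores)}"
            )
        elif mode not in ("complete", "toy"):
            raise ValueError(f"unknown mode {mode!r}")
        return cls(scores, source_label or str(path))

    def to_tsv(self, path: str | Path, header: bool = True) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if header:
                fh.write("hexamer\tscore\n")
            for h in sorted(self.scores):
                fh.write(f"{h}\t{self.scores[h]!r}\n")
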