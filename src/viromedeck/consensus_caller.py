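"""Reference-guided consensus calling from a per-position pileup.

An isolate belonging to an already described species is reconstructed
against its closest reference: at every position with read depth of at
least ``min_depth`` (default 5) where the majority base differs from the
reference, the majority base is substituted and recorded as a variant;
everywhere else — low depth, agreement, or no coverage at all — the
reference base is kept.  The model is substitution-only, so the consensus
always has the reference's length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .formats_io import PileupColumn

__all__ = [
    "Variant",
    "ConsensusResult",
    "call_consensus",
    "variant_table",
    "write_variant_table",
    "read_variant_table",
    "DEFAULT_MIN_DEPTH",
]

DEFAULT_MIN_DEPTH = 5

#: per-position provenance flags
REFERENCE_KEPT = "reference_kept"
VARIANT_CALLED = "variant_called"
NO_COVERAGE = "no_coverage"


@dataclass(frozen=True)
class Variant:
    position: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_fraction: float
    ambiguous: bool = False  # majority tie resolved lexicographically


@dataclass
class ConsensusResult:
    consensus: str
    variants: list[Variant] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)  # one per position

    def __post_init__(self) -> None:
        if len(self.flags) != len(self.consensus):
            raise ValueError("flags length must equal consensus length")


def _majority_base(col: PileupColumn) -> tuple[str, bool]:
    """Majority base of a pileup column.

    Ties keep the reference base when it participates in the tie, otherwise
    the lexicographically smallest tied base wins and the call is flagged
    ambiguous.
    """
    top = max(col.counts.values())
    tied = sorted(b for b, n in col.counts.items() if n == top)
    if len(tied) == 1:
        return tied[0], False
    if col.ref_base in tied:
        return col.ref_base, False
    return tied[0], True


def call_consensus(
    pileup: Sequence[PileupColumn], reference: str, min_depth: int = DEFAULT_MIN_DEPTH
) -> ConsensusResult:
    """Apply the depth-thresholded majority rule along the reference.

    The boundary is inclusive: depth exactly ``min_depth`` is sufficient to
    call a variant, depth ``min_depth - 1`` is not.  Positions absent from
    the pileup keep the reference base and are flagged ``no_coverage``.
    With ``min_depth`` above any observed depth the consensus is the
    reference itself.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    length = len(reference)
    by_pos: dict[int, PileupColumn] = {}
    for col in pileup:
        if col.position > length:
            raise ValueError(
                f"pileup position {col.position} exceeds reference length {length}"
            )
        by_pos[col.position] = col

    bases = list(reference.upper())
    flags = [NO_COVERAGE] * length
    variants: list[Variant] = []
    for pos, col in sorted(by_pos.items()):
        ref_base = bases[pos - 1]
        depth = col.depth
        if depth == 0:
            continue  # a covered-but-empty column behaves like no coverage
        flags[pos - 1] = REFERENCE_KEPT
        if depth < min_depth:
            continue
        majority, ambiguous = _majority_base(col)
        if majority == ref_base or majority == "N":
            continue
        bases[pos - 1] = majority
        flags[pos - 1] = VARIANT_CALLED
        variants.append(
            Variant(
                position=pos,
                ref=ref_base,
                alt=majority,
                depth=depth,
                alt_fraction=col.counts.get(majority, 0) / depth,
                ambiguous=ambiguous,
            )
        )
    return ConsensusResult(consensus="".join(bases), variants=variants, flags=flags)


_VARIANT_COLUMNS = ["position", "ref", "alt", "depth", "alt_fraction", "ambiguous"]


def variant_table(result: ConsensusResult) -> pd.DataFrame:
    """One row per called variant, sorted by position."""
    rows = [
        {
            "position": v.position,
            "ref": v.ref,
            "alt": v.alt,
            "depth": v.depth,
            "alt_fraction": v.alt_fraction,
            "ambiguous": v.ambiguous,
        }
        for v in sorted(result.variants, key=lambda v: v.position)
    ]
    return pd.DataFrame(rows, columns=_VARIANT_COLUMNS)


def write_variant_table(result: ConsensusResult, path: str | Path) -> None:
    variant_table(result).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    if list(df.columns) != _VARIANT_COLUMNS:
        raise ValueError(f"{path}: unexpected variant table columns {list(df.columns)}")
    return [
        Variant(
            position=int(r.position),
            ref=r.ref,
            alt=r.alt,
            depth=int(r.depth),
            alt_fraction=float(r.alt_fraction),
            ambiguous=bool(r.ambiguous),
        )
        for r in df.itertuples()
    ]
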