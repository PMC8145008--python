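"""From alignment hits to confirmed viral contigs and family-level counts.

Candidate viral contigs come from a search against a viral-only database;
because that database contains no cellular sequences, cellular contigs can
acquire spurious viral best hits.  The reciprocal search against a
comprehensive database exposes them: a contig whose best comprehensive hit
is cellular is a likely false positive and is rejected.  Confirmed contigs
are then aggregated into a family-level count table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import CountTable, HitRecord

__all__ = [
    "filter_hits_by_evalue",
    "best_hit_per_query",
    "reciprocal_confirmation",
    "ConfirmationResult",
    "bin_to_families",
    "DEFAULT_FORWARD_CUTOFF",
    "DEFAULT_REVERSE_CUTOFF",
]

#: e-value cutoffs of the forward (viral db) and reverse (comprehensive db)
#: searches; both strict ("< cutoff").
DEFAULT_FORWARD_CUTOFF = 1e-5
DEFAULT_REVERSE_CUTOFF = 1e-3


def filter_hits_by_evalue(hits: Iterable[HitRecord], cutoff: float) -> list[HitRecord]:
    """Retain exactly the hits with ``e_value < cutoff`` (strict inequality)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return [h for h in hits if h.e_value < cutoff]


def best_hit_per_query(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query: lowest e-value, ties broken by highest bit score,
    then lexicographically smallest subject id (fully deterministic)."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.e_value, -h.bit_score, h.subject_id) < (
            cur.e_value,
            -cur.bit_score,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return best


@dataclass
class ConfirmationResult:
    """Outcome of reciprocal confirmation.

    ``confirmed`` lists contigs whose best reverse hit is viral and passes
    the cutoff.  Contigs with no reverse hit at all are retained (silence is
    not contradiction) but flagged separately in ``unconfirmed_no_reverse``.
    ``retained`` is their union, in sorted order.  ``report`` has one row per
    forward contig with its status and cause.
    """

    confirmed: list[str] = field(default_factory=list)
    unconfirmed_no_reverse: list[str] = field(default_factory=list)
    report: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def retained(self) -> list[str]:
        return sorted(set(self.confirmed) | set(self.unconfirmed_no_reverse))

    @property
    def rejected(self) -> list[str]:
        if self.report.empty:
            return []
        return sorted(self.report.loc[self.report["status"] == "rejected", "contig_id"])


def reciprocal_confirmation(
    forward_hits: Sequence[HitRecord],
    reverse_hits: Sequence[HitRecord],
    reverse_cutoff: float = DEFAULT_REVERSE_CUTOFF,
) -> ConfirmationResult:
    """Confirm candidate viral contigs by their reverse best hits.

    A contig is confirmed iff its best reverse hit (lowest e-value, ties by
    highest bit score) has ``e_value < reverse_cutoff`` *and* carries viral
    subject taxonomy.  A contig whose best reverse hit is cellular, or viral
    but too weak, is rejected with the cause recorded.  ``forward_hits`` are
    expected to be e-value-filtered already.

    Raises ``ValueError`` if the reverse table mentions a contig absent from
    the forward table (the reverse search queries only forward survivors).
    """
    forward_ids = {h.query_id for h in forward_hits}
    stray = {h.query_id for h in reverse_hits} - forward_ids
    if stray:
        raise ValueError(
            f"reverse table contains contig(s) absent from forward table: {sorted(stray)}"
        )

    best_reverse = best_hit_per_query(reverse_hits)
    result = ConfirmationResult()
    rows: list[dict[str, object]] = []
    for cid in sorted(forward_ids):
        best = best_reverse.get(cid)
        if best is None:
            result.unconfirmed_no_reverse.append(cid)
            rows.append(
                {
                    "contig_id": cid,
                    "status": "retained",
                    "cause": "unconfirmed-no-reverse-hit",
                    "best_reverse_subject": "",
                    "best_reverse_evalue": float("nan"),
                }
            )
            continue
        if not best.is_viral:
            status, cause = "rejected", "best-reverse-hit-cellular"
        elif best.e_value >= reverse_cutoff:
            status, cause = "rejected", "best-reverse-hit-above-cutoff"
        else:
            status, cause = "confirmed", "best-reverse-hit-viral"
            result.confirmed.append(cid)
        rows.append(
            {
                "contig_id": cid,
                "status": status,
                "cause": cause,
                "best_reverse_subject": best.subject_id,
                "best_reverse_evalue": best.e_value,
            }
        )
    result.report = pd.DataFrame(
        rows,
        columns=["contig_id", "status", "cause", "best_reverse_subject", "best_reverse_evalue"],
    )
    return result


def bin_to_families(
    contig_counts: pd.DataFrame,
    contig_family: Mapping[str, str],
    retained_contigs: Iterable[str] | None = None,
    allow_unknown: bool = False,
) -> pd.DataFrame:
    """Aggregate per-contig read counts into per-family counts.

    Parameters
    ----------
    contig_counts
        contigs x samples integer DataFrame.
    contig_family
        Mapping contig id -> family name; every contig must map to exactly
        one family unless ``allow_unknown`` (unknown contigs then dropped).
    retained_contigs
        Optional subset (e.g. the output of reciprocal confirmation); other
        contigs are excluded before aggregation.

    Family counts are the per-sample sums of their contigs' counts, so read
    totals are conserved when no contig is unknown.
    """
    counts = contig_counts
    if retained_contigs is not None:
        keep = [c for c in counts.index if c in set(retained_contigs)]
        counts = counts.loc[keep]
    unknown = [c for c in counts.index if c not in contig_family]
    if unknown and not allow_unknown:
        raise ValueError(f"contig(s) with unknown family: {sorted(unknown)}")
    counts = counts.drop(index=unknown)
    families = pd.Series({c: contig_family[c] for c in counts.index}, name="family")
    out = counts.groupby(families).sum()
    out.index.name = "family"
    return out.sort_index()


def family_table_from_contigs(
    contig_counts: pd.DataFrame,
    contig_family: Mapping[str, str],
    samples: pd.DataFrame,
    taxa: pd.DataFrame | None = None,
    retained_contigs: Iterable[str] | None = None,
    allow_unknown: bool = False,
) -> CountTable:
    """Convenience wrapper returning a full :class:`CountTable`."""
    fam = bin_to_families(contig_counts, contig_family, retained_contigs, allow_unknown)
    return CountTable(counts=fam, samples=samples, taxa=taxa)
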