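"""Species demarcation of viral contigs against ICTV family thresholds.

A reconstructed viral genome is compared with its closest known relative.
Near-identity at the whole-genome nucleotide level (at or above the
known-isolate floor, default 98%) makes it a new isolate of a known
species.  Otherwise, where the family has a published demarcation
criterion, identity on the designated marker protein strictly below the
family threshold makes it a novel species; families without a criterion
can only yield "putative novel, no criterion" when the best marker
identity falls below a conservative novelty floor (default 60% aa),
and "indeterminate" in the gap between the two regimes.

Shipped rules follow the current ICTV reports for the two families the
package's target surveys demarcate most often:

* Alphaflexiviridae — distinct species below 80% aa identity in the capsid
  *or* polymerase proteins;
* Iflaviridae — distinct species below 90% aa identity in the capsid
  proteins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .formats_io import DemarcationRule

__all__ = [
    "ContigEvidence",
    "Verdict",
    "load_default_rules",
    "merge_rules",
    "classify_demarcation",
    "summarize_discovery",
    "KNOWN_ISOLATE",
    "KNOWN_STRAIN",
    "NOVEL_SPECIES",
    "PUTATIVE_NOVEL_NO_CRITERION",
    "INDETERMINATE",
    "DEFAULT_KNOWN_ISOLATE_FLOOR",
    "DEFAULT_NOVELTY_FLOOR",
]

KNOWN_ISOLATE = "known_isolate"
KNOWN_STRAIN = "known_strain"
NOVEL_SPECIES = "novel_species"
PUTATIVE_NOVEL_NO_CRITERION = "putative_novel_no_criterion"
INDETERMINATE = "indeterminate"

#: nt whole-genome identity at or above which a contig is a new isolate of a
#: known species; chosen just below the 98.2% minimum observed for known
#: isolates in the surveys this package targets.
DEFAULT_KNOWN_ISOLATE_FLOOR = 98.0
#: best aa identity below which a contig from a rule-less family is called
#: putatively novel; chosen just above the 57.2% maximum observed for novel
#: genomes in those surveys.
DEFAULT_NOVELTY_FLOOR = 60.0


@dataclass(frozen=True)
class ContigEvidence:
    """Identity evidence for one contig against its closest relative."""

    contig_id: str
    family: str
    marker_identities: dict[str, float] = field(default_factory=dict)
    closest_relative_id: str = ""
    nt_genome_identity: float | None = None
    host_class: str = "unknown"

    def __post_init__(self) -> None:
        for marker, ident in self.marker_identities.items():
            if not 0.0 <= ident <= 100.0:
                raise ValueError(
                    f"identity {ident} for marker {marker!r} outside [0, 100] "
                    f"(contig {self.contig_id!r})"
                )
        if self.nt_genome_identity is not None and not 0.0 <= self.nt_genome_identity <= 100.0:
            raise ValueError(f"nt genome identity outside [0, 100] (contig {self.contig_id!r})")


@dataclass(frozen=True)
class Verdict:
    contig_id: str
    verdict: str
    rationale: str


def load_default_rules() -> list[DemarcationRule]:
    """The two shipped family rules; all other families have no criterion."""
    return [
        DemarcationRule("Alphaflexiviridae", "capsid_or_polymerase", "aa", 80.0),
        DemarcationRule("Iflaviridae", "capsid", "aa", 90.0),
    ]


def merge_rules(
    base: Sequence[DemarcationRule], overrides: Sequence[DemarcationRule]
) -> list[DemarcationRule]:
    """Overrides replace base rules for the same family (user TSV wins)."""
    merged = {r.family: r for r in base}
    for r in overrides:
        merged[r.family] = r
    return list(merged.values())


def _rule_for(family: str, rules: Sequence[DemarcationRule]) -> DemarcationRule | None:
    for r in rules:
        if r.family == family:
            return r
    return None


def classify_demarcation(
    evidence: ContigEvidence,
    rules: Sequence[DemarcationRule] | None = None,
    known_isolate_floor: float = DEFAULT_KNOWN_ISOLATE_FLOOR,
    novelty_floor: float = DEFAULT_NOVELTY_FLOOR,
    or_marker_semantics: str = "both",
) -> Verdict:
    """Classify one contig.

    Decision order: known isolate (whole-genome nt identity at or above the
    floor, inclusive); then the family rule, when one exists, with identity
    strictly below the threshold meaning novel species; then the rule-less
    novelty floor.  For a ``capsid_or_polymerase`` rule,
    ``or_marker_semantics='both'`` (conservative) requires every supplied
    marker to fall below the threshold, ``'either'`` requires any.

    Raises ``ValueError`` when a family rule exists but the required marker
    identity was not supplied.
    """
    if or_marker_semantics not in ("both", "either"):
        raise ValueError("or_marker_semantics must be 'both' or 'either'")
    rules = list(rules) if rules is not None else load_default_rules()

    if evidence.nt_genome_identity is not None and evidence.nt_genome_identity >= known_isolate_floor:
        return Verdict(
            evidence.contig_id,
            KNOWN_ISOLATE,
            f"whole-genome nt identity {evidence.nt_genome_identity:.1f}% "
            f">= {known_isolate_floor}% to {evidence.closest_relative_id or 'closest relative'}",
        )

    rule = _rule_for(evidence.family, rules)
    if rule is not None:
        if rule.marker == "capsid_or_polymerase":
            supplied = {
                m: v for m, v in evidence.marker_identities.items() if m in ("capsid", "polymerase")
            }
            if not supplied:
                raise ValueError(
                    f"contig {evidence.contig_id!r}: family {evidence.family!r} rule needs "
                    "capsid and/or polymerase identity"
                )
            below = [v < rule.threshold_pct for v in supplied.values()]
            is_novel = all(below) if or_marker_semantics == "both" else any(below)
            shown = ", ".join(f"{m} {v:.1f}%" for m, v in sorted(supplied.items()))
        else:
            if rule.marker not in evidence.marker_identities:
                raise ValueError(
                    f"contig {evidence.contig_id!r}: family {evidence.family!r} rule needs "
                    f"{rule.marker!r} identity"
                )
            v = evidence.marker_identities[rule.marker]
            is_novel = v < rule.threshold_pct
            shown = f"{rule.marker} {v:.1f}%"
        if is_novel:
            return Verdict(
                evidence.contig_id,
                NOVEL_SPECIES,
                f"{shown} below the {evidence.family} demarcation threshold "
                f"of {rule.threshold_pct}% {rule.level}",
            )
        return Verdict(
            evidence.contig_id,
            KNOWN_STRAIN,
            f"{shown} at or above the {evidence.family} demarcation threshold "
            f"of {rule.threshold_pct}% {rule.level}: strain of a known species",
        )

    if not evidence.marker_identities:
        raise ValueError(
            f"contig {evidence.contig_id!r}: no family rule and no marker identity supplied"
        )
    best = max(evidence.marker_identities.values())
    if best < novelty_floor:
        return Verdict(
            evidence.contig_id,
            PUTATIVE_NOVEL_NO_CRITERION,
            f"family {evidence.family!r} has no demarcation criterion and the best "
            f"marker identity {best:.1f}% is below the novelty floor of {novelty_floor}%",
        )
    return Verdict(
        evidence.contig_id,
        INDETERMINATE,
        f"family {evidence.family!r} has no demarcation criterion and the best "
        f"marker identity {best:.1f}% is at or above the novelty floor of {novelty_floor}%",
    )


_MARKER_COLUMNS = ("capsid", "polymerase", "polyprotein", "genome_nt")


def read_evidence(path) -> list[ContigEvidence]:
    """Read contig evidence from TSV.

    Required columns: ``contig_id``, ``family``; optional:
    ``closest_relative_id``, ``host_class``, ``nt_genome_identity`` and one
    column per marker (``capsid``, ``polymerase``, ``polyprotein``,
    ``genome_nt``).  Empty cells mean "not measured".
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "family": str})
    for col in ("contig_id", "family"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out: list[ContigEvidence] = []
    for row in df.itertuples(index=False):
        markers = {
            m: float(getattr(row, m))
            for m in _MARKER_COLUMNS
            if m in df.columns and pd.notna(getattr(row, m))
        }
        nt = getattr(row, "nt_genome_identity", None)
        out.append(
            ContigEvidence(
                contig_id=row.contig_id,
                family=row.family,
                marker_identities=markers,
                closest_relative_id=str(getattr(row, "closest_relative_id", "") or ""),
                nt_genome_identity=None if nt is None or pd.isna(nt) else float(nt),
                host_class=str(getattr(row, "host_class", "unknown") or "unknown"),
            )
        )
    return out


def summarize_discovery(
    evidence_list: Iterable[ContigEvidence],
    rules: Sequence[DemarcationRule] | None = None,
    **classify_kwargs,
) -> dict:
    """Discovery counts over a set of classified contigs.

    ``known_species`` deduplicates closest relatives among known-isolate
    contigs (two contigs matching the same species count once);
    ``novel_total`` counts contigs called novel with or without a family
    criterion, split by declared host class in ``novel_by_host_class``.
    """
    verdicts: list[tuple[ContigEvidence, Verdict]] = [
        (ev, classify_demarcation(ev, rules, **classify_kwargs)) for ev in evidence_list
    ]
    known = [ev for ev, v in verdicts if v.verdict == KNOWN_ISOLATE]
    novel = [ev for ev, v in verdicts if v.verdict in (NOVEL_SPECIES, PUTATIVE_NOVEL_NO_CRITERION)]
    by_class = Counter(ev.host_class for ev in novel)
    return {
        "n_contigs": len(verdicts),
        "known_isolates": len(known),
        "known_species": len({ev.closest_relative_id for ev in known}),
        "novel_species": sum(1 for _, v in verdicts if v.verdict == NOVEL_SPECIES),
        "novel_no_criterion": sum(
            1 for _, v in verdicts if v.verdict == PUTATIVE_NOVEL_NO_CRITERION
        ),
        "novel_total": len(novel),
        "known_strains": sum(1 for _, v in verdicts if v.verdict == KNOWN_STRAIN),
        "indeterminate": sum(1 for _, v in verdicts if v.verdict == INDETERMINATE),
        "novel_by_host_class": dict(by_class),
        "verdicts": pd.DataFrame(
            [
                {"contig_id": v.contig_id, "verdict": v.verdict, "rationale": v.rationale}
                for _, v in verdicts
            ],
            columns=["contig_id", "verdict", "rationale"],
        ),
    }
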