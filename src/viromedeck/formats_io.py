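"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are plain TSV so that outputs are diffable and the whole
artifact stays download-free.  Readers validate strictly and raise
:class:`FormatError` (with a line number where one makes sense) instead of
silently coercing malformed input.

Conventions
-----------
* Sequence coordinates are 1-based and inclusive everywhere.
* FASTA output wraps at 70 columns; a record id is the first
  whitespace-delimited token of the header.
* Alignment hit tables follow the standard 12-field BLAST tabular layout
  with the subject taxonomy label appended as field 13.
* Pileups are a bespoke 7-column TSV (``pos ref A C G T N``); a converter
  from ``samtools mpileup`` text output is a documented extension point,
  not part of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "CountTable",
    "HitRecord",
    "PileupColumn",
    "DemarcationRule",
    "VALID_ROLES",
    "VALID_HOST_CLASSES",
    "VALID_MARKERS",
    "read_count_table",
    "write_count_table",
    "read_fasta",
    "write_fasta",
    "read_hits",
    "write_hits",
    "read_pileup",
    "write_pileup",
    "read_rules",
    "write_rules",
]

VALID_ROLES = frozenset({"specimen", "negative_control"})
VALID_HOST_CLASSES = frozenset({"arthropod", "plant_fungus", "phage", "unknown"})
VALID_MARKERS = frozenset(
    {"capsid", "polymerase", "capsid_or_polymerase", "polyprotein", "genome_nt"}
)
PILEUP_BASES = ("A", "C", "G", "T", "N")

# IUPAC nucleotide codes, used to validate sequences and primers.
IUPAC_CODES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class FormatError(ValueError):
    """Raised when an on-disk file fails validation."""


# ---------------------------------------------------------------------------
# Count table
# ---------------------------------------------------------------------------

#: metadata rows embedded in a count-table TSV, in writing order
_META_ROWS = ("role", "host", "habitat", "total_cleaned_reads")


@dataclass
class CountTable:
    """A taxa x samples read-count matrix with sample and taxon metadata.

    Attributes
    ----------
    counts
        Integer DataFrame, rows indexed by taxon id, columns by sample id.
    samples
        DataFrame indexed by sample id with columns ``role`` (``specimen`` or
        ``negative_control``), ``host``, ``habitat`` and
        ``total_cleaned_reads`` (the post-QC library size used as the
        denominator of relative abundances).
    taxa
        Optional DataFrame indexed by taxon id with columns ``family``,
        ``host_class`` and ``contig_length_kb``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    taxa: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate taxon id(s): {dupes}")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample id(s): {dupes}")
        if (self.counts.values < 0).any():
            t, s = [
                (self.counts.index[i], self.counts.columns[j])
                for i, j in zip(*(self.counts.values < 0).nonzero())
            ][0]
            raise FormatError(f"negative count at taxon={t!r}, sample={s!r}")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)}")
        bad_roles = set(self.samples["role"]) - VALID_ROLES
        if bad_roles:
            raise FormatError(f"unknown sample role(s): {sorted(bad_roles)}")
        if self.taxa is not None:
            bad_hc = set(self.taxa.get("host_class", pd.Series(dtype=object))) - VALID_HOST_CLASSES
            if bad_hc:
                raise FormatError(f"unknown host class(es): {sorted(bad_hc)}")

    # -- convenience views ---------------------------------------------------

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["role"] == "specimen"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["role"] == "negative_control"])

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by each sample's total cleaned reads."""
        totals = self.samples.loc[self.counts.columns, "total_cleaned_reads"].astype(float)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise FormatError(f"non-positive total_cleaned_reads for sample(s): {bad}")
        return self.counts.astype(float) / totals

    def copy(self) -> "CountTable":
        return CountTable(
            counts=self.counts.copy(),
            samples=self.samples.copy(),
            taxa=None if self.taxa is None else self.taxa.copy(),
        )


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table as TSV.

    Layout: a header row of sample ids, four ``#``-prefixed metadata rows
    (role, host, habitat, total_cleaned_reads) and then one integer row per
    taxon, in a stable (current index) order.
    """
    path = Path(path)
    with path.open("w") as fh:
        cols = list(table.counts.columns)
        fh.write("taxon_id\t" + "\t".join(cols) + "\n")
        for meta in _META_ROWS:
            vals = table.samples.loc[cols, meta]
            fh.write(f"#{meta}\t" + "\t".join(str(v) for v in vals) + "\n")
        for taxon, row in table.counts.iterrows():
            fh.write(str(taxon) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_count_table(path: str | Path) -> CountTable:
    """Read a count table written by :func:`write_count_table`.

    Raises :class:`FormatError` naming the offending cell on negative or
    non-integer counts, duplicate ids, or unknown role values.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "taxon_id":
        raise FormatError(f"{path}:1: first column must be 'taxon_id'")
    sample_ids = header[1:]
    meta: dict[str, list[str]] = {}
    row_idx = 1
    while row_idx < len(lines) and lines[row_idx].startswith("#"):
        fields = lines[row_idx].split("\t")
        key = fields[0][1:]
        if key not in _META_ROWS:
            raise FormatError(f"{path}:{row_idx + 1}: unknown metadata row {key!r}")
        if len(fields) - 1 != len(sample_ids):
            raise FormatError(f"{path}:{row_idx + 1}: wrong number of fields")
        meta[key] = fields[1:]
        row_idx += 1
    missing = [m for m in _META_ROWS if m not in meta]
    if missing:
        raise FormatError(f"{path}: missing metadata row(s): {missing}")

    taxa_ids: list[str] = []
    data: list[list[int]] = []
    for ln in range(row_idx, len(lines)):
        fields = lines[ln].split("\t")
        if len(fields) - 1 != len(sample_ids):
            raise FormatError(f"{path}:{ln + 1}: wrong number of fields")
        taxa_ids.append(fields[0])
        row: list[int] = []
        for s_id, raw in zip(sample_ids, fields[1:]):
            try:
                val = int(raw)
            except ValueError:
                raise FormatError(
                    f"{path}:{ln + 1}: non-integer count {raw!r} "
                    f"(taxon={fields[0]!r}, sample={s_id!r})"
                ) from None
            if val < 0:
                raise FormatError(
                    f"{path}:{ln + 1}: negative count {val} "
                    f"(taxon={fields[0]!r}, sample={s_id!r})"
                )
            row.append(val)
        data.append(row)

    counts = pd.DataFrame(data, index=pd.Index(taxa_ids, name="taxon_id"), columns=sample_ids)
    try:
        totals = [int(v) for v in meta["total_cleaned_reads"]]
    except ValueError:
        raise FormatError(f"{path}: non-integer total_cleaned_reads") from None
    samples = pd.DataFrame(
        {
            "role": meta["role"],
            "host": meta["host"],
            "habitat": meta["habitat"],
            "total_cleaned_reads": totals,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountTable(counts=counts, samples=samples)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict (sequences uppercased)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with Path(path).open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Alignment hit tables (BLAST tabular + taxonomy column)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12+1-column alignment tabular file."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    subject_taxonomy: str

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise FormatError(f"negative e-value {self.e_value} for query {self.query_id!r}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise FormatError(
                f"percent identity {self.percent_identity} outside [0, 100] "
                f"for query {self.query_id!r}"
            )

    @property
    def is_viral(self) -> bool:
        """True when the taxonomy label's top-level token is ``Viruses``."""
        return self.subject_taxonomy.split(";")[0].strip() == "Viruses"


_HIT_FIELDS = 13


def read_hits(path: str | Path) -> list[HitRecord]:
    path = Path(path)
    hits: list[HitRecord] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != _HIT_FIELDS:
            raise FormatError(f"{path}:{ln}: expected {_HIT_FIELDS} fields, got {len(fields)}")
        try:
            rec = HitRecord(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=float(fields[2]),
                alignment_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                e_value=float(fields[10]),
                bit_score=float(fields[11]),
                subject_taxonomy=fields[12],
            )
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from None
        hits.append(rec)
    return hits


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        h.percent_identity,
                        h.alignment_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        h.e_value,
                        h.bit_score,
                        h.subject_taxonomy,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PileupColumn:
    """Per-position base counts over a reference (1-based coordinate)."""

    position: int
    ref_base: str
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"pileup position {self.position} is not 1-based")
        if self.ref_base not in PILEUP_BASES:
            raise FormatError(f"pileup reference base {self.ref_base!r} not in {PILEUP_BASES}")
        for base, n in self.counts.items():
            if base not in PILEUP_BASES:
                raise FormatError(f"pileup count for non-IUPAC base {base!r}")
            if n < 0:
                raise FormatError(f"negative pileup count at position {self.position}")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def read_pileup(path: str | Path) -> list[PileupColumn]:
    path = Path(path)
    columns: list[PileupColumn] = []
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != ["pos", "ref", *PILEUP_BASES]:
        raise FormatError(f"{path}:1: expected header 'pos\tref\tA\tC\tG\tT\tN'")
    last_pos = 0
    for ln, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 7:
            raise FormatError(f"{path}:{ln}: expected 7 fields, got {len(fields)}")
        try:
            pos = int(fields[0])
            counts = {b: int(v) for b, v in zip(PILEUP_BASES, fields[2:])}
            col = PileupColumn(position=pos, ref_base=fields[1], counts=counts)
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from None
        if pos <= last_pos:
            raise FormatError(
                f"{path}:{ln}: positions must be strictly increasing "
                f"({pos} after {last_pos})"
            )
        last_pos = pos
        columns.append(col)
    return columns


def write_pileup(columns: Sequence[PileupColumn], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("pos\tref\t" + "\t".join(PILEUP_BASES) + "\n")
        for col in columns:
            fh.write(
                f"{col.position}\t{col.ref_base}\t"
                + "\t".join(str(col.counts.get(b, 0)) for b in PILEUP_BASES)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Demarcation rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemarcationRule:
    """A family-specific species demarcation threshold.

    Identity *below* ``threshold_pct`` on the stated marker (at the stated
    sequence level) means two viruses are distinct species.
    """

    family: str
    marker: str
    level: str
    threshold_pct: float

    def __post_init__(self) -> None:
        if self.marker not in VALID_MARKERS:
            raise FormatError(f"unknown marker {self.marker!r}")
        if self.level not in ("nt", "aa"):
            raise FormatError(f"level must be 'nt' or 'aa', got {self.level!r}")
        if not 0.0 < self.threshold_pct < 100.0:
            raise FormatError(
                f"threshold_pct {self.threshold_pct} outside (0, 100) "
                f"for family {self.family!r}"
            )


_RULES_HEADER = ["family", "marker", "level", "threshold_pct"]


def read_rules(path: str | Path) -> list[DemarcationRule]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != _RULES_HEADER:
        raise FormatError(f"{path}:1: expected header columns {_RULES_HEADER}")
    rules: list[DemarcationRule] = []
    seen: set[tuple[str, str]] = set()
    for ln, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"{path}:{ln}: expected 4 fields, got {len(fields)}")
        try:
            rule = DemarcationRule(fields[0], fields[1], fields[2], float(fields[3]))
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from None
        key = (rule.family, rule.marker)
        if key in seen:
            raise FormatError(f"{path}:{ln}: duplicate rule for {key}")
        seen.add(key)
        rules.append(rule)
    return rules


def write_rules(rules: Iterable[DemarcationRule], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_RULES_HEADER) + "\n")
        for r in rules:
            fh.write(f"{r.family}\t{r.marker}\t{r.level}\t{r.threshold_pct}\n")
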