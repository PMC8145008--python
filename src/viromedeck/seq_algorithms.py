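"""Sequence-level algorithms: global alignment, identity, ORFs, in-silico PCR.

The global aligner is an affine-gap Needleman-Wunsch (Gotoh) with a fully
deterministic traceback, used to compute SDT-style pairwise identities for
species demarcation.  ORF scanning applies the survey convention (ATG
start, in-sequence stop, length strictly above the cutoff, longest start
per stop), and in-silico PCR locates degenerate primer sites under IUPAC
matching and reports both the 5'-to-5' region length and the inclusive
product length, because the two conventions are easy to confuse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping
import warnings

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .formats_io import IUPAC_CODES

__all__ = [
    "AlignmentScoring",
    "Alignment",
    "global_align",
    "pairwise_identity",
    "identity_matrix",
    "OrfRecord",
    "find_orfs",
    "cds_completeness",
    "AmpliconResult",
    "in_silico_pcr",
    "reverse_complement",
    "NT_SCORING",
    "AA_SCORING",
]

_NT_ALPHABET = frozenset("ACGTN")
GAP = "-"


@dataclass(frozen=True)
class AlignmentScoring:
    """Scoring scheme for global alignment.

    Gap penalties are stored as positive costs; a gap of length L is
    penalised ``gap_open + L * gap_extend``.  At the ``aa`` level a named
    log-odds substitution matrix replaces match/mismatch.
    """

    level: str = "nt"  # "nt" | "aa"
    match: float = 2.0
    mismatch: float = -3.0
    matrix_name: str = "BLOSUM62"
    gap_open: float = 5.0
    gap_extend: float = 2.0

    def __post_init__(self) -> None:
        if self.level not in ("nt", "aa"):
            raise ValueError("level must be 'nt' or 'aa'")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are stored as non-negative costs")

    def substitution(self, a: str, b: str) -> float:
        if self.level == "nt":
            return self.match if a == b else self.mismatch
        return float(_load_matrix(self.matrix_name)[a, b])


NT_SCORING = AlignmentScoring()
AA_SCORING = AlignmentScoring(level="aa", gap_open=11.0, gap_extend=1.0)

_MATRIX_CACHE: dict[str, object] = {}


def _load_matrix(name: str):
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal gapped length")


def _validate_alphabet(seq: str, scoring: AlignmentScoring) -> None:
    if not seq:
        raise ValueError("sequences must be non-empty")
    if scoring.level == "nt":
        bad = set(seq) - _NT_ALPHABET
        if bad:
            raise ValueError(f"illegal nucleotide character(s): {sorted(bad)}")
    else:
        alphabet = set(str(_load_matrix(scoring.matrix_name).alphabet))
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(f"character(s) outside substitution matrix alphabet: {sorted(bad)}")


def global_align(a: str, b: str, scoring: AlignmentScoring = NT_SCORING) -> Alignment:
    """Optimal global alignment under affine gap costs (Gotoh algorithm).

    Three dynamic-programming layers track alignments ending in a
    match/mismatch (M), a gap in ``b`` (X, consuming ``a``) or a gap in
    ``a`` (Y, consuming ``b``).  The traceback prefers M over X over Y at
    score ties, which makes the reported alignment deterministic.
    """
    a = a.upper()
    b = b.upper()
    _validate_alphabet(a, scoring)
    _validate_alphabet(b, scoring)
    n, m = len(a), len(b)
    go, ge = scoring.gap_open, scoring.gap_extend
    neg = float("-inf")

    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + i * ge)
    for j in range(1, m + 1):
        Y[0, j] = -(go + j * ge)

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = scoring.substitution(ai, b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - go - ge, X[i - 1, j] - ge, Y[i - 1, j] - go - ge)
            Y[i, j] = max(M[i, j - 1] - go - ge, Y[i, j - 1] - ge, X[i, j - 1] - go - ge)

    # Traceback: state preference M > X > Y at every tie.
    i, j = n, m
    final = {"M": M[n, m], "X": X[n, m], "Y": Y[n, m]}
    score = float(max(final.values()))
    state = next(st for st in ("M", "X", "Y") if final[st] == score)
    out_a: list[str] = []
    out_b: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = scoring.substitution(a[i - 1], b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            for st, layer in (("M", M), ("X", X), ("Y", Y)):
                if abs(layer[i, j] - target) < tol:
                    state = st
                    break
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            val = X[i, j]
            i -= 1
            if abs(M[i, j] - go - ge - val) < tol:
                state = "M"
            elif abs(X[i, j] - ge - val) < tol:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if abs(M[i, j] - go - ge - val) < tol:
                state = "M"
            elif abs(Y[i, j] - ge - val) < tol:
                state = "Y"
            else:
                state = "X"
    return Alignment(aligned_a="".join(reversed(out_a)), aligned_b="".join(reversed(out_b)), score=score)


# ---------------------------------------------------------------------------
# Identity
# ---------------------------------------------------------------------------

GAP_POLICIES = ("sdt", "exclude_gaps", "include_gaps")


def pairwise_identity(alignment: Alignment, gap_policy: str = "sdt") -> float:
    """Percent identity of an aligned pair.

    Policies
    --------
    ``sdt`` (default)
        Terminal-gap columns (overhangs) are excluded; internal gap columns
        count as mismatched columns.
    ``exclude_gaps``
        Every gap column is excluded from the denominator.
    ``include_gaps``
        Every column counts.
    """
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"gap_policy must be one of {GAP_POLICIES}")
    a, b = alignment.aligned_a, alignment.aligned_b
    start, end = 0, len(a)
    if gap_policy == "sdt":
        while start < end and (a[start] == GAP or b[start] == GAP):
            start += 1
        while end > start and (a[end - 1] == GAP or b[end - 1] == GAP):
            end -= 1
    matches = 0
    counted = 0
    for x, y in zip(a[start:end], b[start:end]):
        is_gap = x == GAP or y == GAP
        if is_gap and gap_policy == "exclude_gaps":
            continue
        counted += 1
        if not is_gap and x == y:
            matches += 1
    if counted == 0:
        return 0.0
    return 100.0 * matches / counted


def identity_matrix(
    sequences: Mapping[str, str],
    scoring: AlignmentScoring = NT_SCORING,
    gap_policy: str = "sdt",
) -> pd.DataFrame:
    """Symmetric all-vs-all percent-identity matrix with a 100.0 diagonal."""
    names = list(sequences)
    if len(names) < 2:
        raise ValueError("need at least two sequences")
    mat = pd.DataFrame(100.0, index=names, columns=names)
    for i, ni in enumerate(names):
        for nj in names[i + 1 :]:
            ident = pairwise_identity(global_align(sequences[ni], sequences[nj], scoring), gap_policy)
            mat.loc[ni, nj] = ident
            mat.loc[nj, ni] = ident
    return mat


# ---------------------------------------------------------------------------
# ORF scanning and CDS completeness
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame; coordinates are 1-based inclusive on the plus
    strand and include the stop codon."""

    start: int
    end: int
    strand: str
    frame: int
    length_nt: int
    protein: str

    def __post_init__(self) -> None:
        if self.length_nt != self.end - self.start + 1:
            raise ValueError("length_nt must equal end - start + 1")
        if self.length_nt % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _scan_strand(seq: str, min_len_nt: int) -> list[tuple[int, int, int]]:
    """(start, end, frame) of ATG..stop ORFs on the given (plus-oriented)
    sequence, longest start per stop, 1-based, length strictly > min_len_nt."""
    found: list[tuple[int, int, int]] = []
    for frame in range(3):
        earliest_atg: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if earliest_atg is not None:
                    start, end = earliest_atg + 1, pos + 3
                    if end - start + 1 > min_len_nt:
                        found.append((start, end, frame + 1))
                    earliest_atg = None
            elif codon == "ATG" and earliest_atg is None:
                earliest_atg = pos
    return found


def find_orfs(seq: str, min_len_nt: int = 300, both_strands: bool = True) -> list[OrfRecord]:
    """Six-frame ORF scan with a strict length cutoff.

    An ORF starts at ATG, ends at an in-frame stop codon inside the
    sequence, and its length (stop codon included) must be strictly greater
    than ``min_len_nt``.  When several ATGs share a stop only the longest
    (5'-most) ORF is reported.  Minus-strand ORFs are reported in
    plus-strand coordinates with ``start < end``.
    """
    seq = seq.upper()
    records: list[OrfRecord] = []
    length = len(seq)
    for start, end, frame in _scan_strand(seq, min_len_nt):
        protein = str(Seq(seq[start - 1 : end - 3]).translate())
        records.append(
            OrfRecord(start=start, end=end, strand="+", frame=frame, length_nt=end - start + 1, protein=protein)
        )
    if both_strands:
        rc = reverse_complement(seq)
        for start, end, frame in _scan_strand(rc, min_len_nt):
            protein = str(Seq(rc[start - 1 : end - 3]).translate())
            records.append(
                OrfRecord(
                    start=length - end + 1,
                    end=length - start + 1,
                    strand="-",
                    frame=frame,
                    length_nt=end - start + 1,
                    protein=protein,
                )
            )
    return sorted(records, key=lambda r: (r.start, r.end, r.strand))


def cds_completeness(recovered_cds_len: int, reference_cds_len: int) -> tuple[float, bool]:
    """Recovered fraction of a reference coding sequence.

    Returns ``(fraction, near_full)`` where ``near_full`` requires the
    fraction to exceed 0.9 strictly — exactly 90% recovered does not
    qualify.  A recovered length above the reference clamps to 1.0 with a
    warning (the two CDSs were measured against different annotations).
    """
    if recovered_cds_len <= 0 or reference_cds_len <= 0:
        raise ValueError("CDS lengths must be positive")
    fraction = recovered_cds_len / reference_cds_len
    if fraction > 1.0:
        warnings.warn(
            f"recovered CDS ({recovered_cds_len}) longer than reference "
            f"({reference_cds_len}); clamping completeness to 1.0",
            stacklevel=2,
        )
        fraction = 1.0
    return fraction, fraction > 0.9


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmpliconResult:
    """A primer pair placement on the plus strand.

    ``fwd_start`` and ``rev_start`` are the 5' ends of the two primers in
    1-based plus-strand coordinates (the reverse primer's 5' end is the
    rightmost base of its binding site).  ``region_length`` is their
    difference — the convention under which a pair named 8007F/9134R
    targets a 1127 nt region — while ``product_length`` is the inclusive
    span ``rev_start - fwd_start + 1``.
    """

    fwd_start: int
    rev_start: int
    region_length: int
    product_length: int
    fwd_mismatches: int = 0
    rev_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.rev_start <= self.fwd_start:
            raise ValueError("rev_start must exceed fwd_start")
        if self.region_length != self.rev_start - self.fwd_start:
            raise ValueError("region_length must equal rev_start - fwd_start")


def _iupac_match(primer_char: str, template_char: str) -> bool:
    p = IUPAC_CODES.get(primer_char)
    t = IUPAC_CODES.get(template_char)
    if p is None or t is None:
        raise ValueError(f"non-IUPAC character in primer or template: {primer_char!r}/{template_char!r}")
    return bool(p & t)


def _primer_sites(template: str, primer: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(1-based start, mismatches) of every primer placement on the template."""
    sites: list[tuple[int, int]] = []
    plen = len(primer)
    for start in range(len(template) - plen + 1):
        mism = 0
        for pc, tc in zip(primer, template[start : start + plen]):
            if not _iupac_match(pc, tc):
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            sites.append((start + 1, mism))
    return sites


def in_silico_pcr(
    template: str, fwd_primer: str, rev_primer: str, max_mismatch: int = 0
) -> list[AmpliconResult]:
    """Locate a degenerate primer pair on a template.

    The forward primer is matched on the plus strand; the reverse primer is
    matched as its reverse complement (its 5' end maps to the rightmost
    plus-strand base of the site).  IUPAC degeneracy counts as a match in
    both primer and template.  Every forward/reverse combination with
    ``rev_start > fwd_start`` is reported; an empty list means no amplicon.
    """
    template = template.upper().replace("U", "T")
    fwd = fwd_primer.upper().replace("U", "T").replace(" ", "")
    rev = rev_primer.upper().replace("U", "T").replace(" ", "")
    for name, p in (("forward", fwd), ("reverse", rev)):
        if len(p) < 10:
            raise ValueError(f"{name} primer shorter than 10 nt")
        bad = set(p) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"{name} primer contains non-IUPAC character(s): {sorted(bad)}")

    fwd_sites = _primer_sites(template, fwd, max_mismatch)
    rc_rev = reverse_complement(rev)
    rev_sites = [
        (start + len(rev) - 1, mism) for start, mism in _primer_sites(template, rc_rev, max_mismatch)
    ]
    results = []
    for f_start, f_mism in fwd_sites:
        for r_start, r_mism in rev_sites:
            if r_start > f_start:
                results.append(
                    AmpliconResult(
                        fwd_start=f_start,
                        rev_start=r_start,
                        region_length=r_start - f_start,
                        product_length=r_start - f_start + 1,
                        fwd_mismatches=f_mism,
                        rev_mismatches=r_mism,
                    )
                )
    return sorted(results, key=lambda r: (r.fwd_start, r.rev_start))
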