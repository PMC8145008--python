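"""Independent brute-force oracles used to validate the implementations.

Each oracle deliberately uses a different formulation from the code it
checks: exhaustive enumeration where feasible, otherwise a plain recursive
restatement of the objective.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np

NEG_INF = float("-inf")


def enumerate_align_score(a: str, b: str, match: float, mismatch: float,
                          gap_open: float, gap_extend: float) -> float:
    """Best global alignment score by full enumeration of alignment paths.

    Exponential: walks every monotone path through the alignment grid,
    charging gap_open + gap_extend at a gap opening and gap_extend at an
    extension.  Use only for very short sequences.
    """

    def go(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG_INF
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + go(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "X" else gap_open + gap_extend
            best = max(best, -cost + go(i + 1, j, "X"))
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open + gap_extend
            best = max(best, -cost + go(i, j + 1, "Y"))
        return best

    return go(0, 0, "M")


def recursive_align_score(a: str, b: str, match: float, mismatch: float,
                          gap_open: float, gap_extend: float) -> float:
    """Memoised three-state recursion for the same objective (feasible to
    length ~dozens); an independent restatement of the affine-gap optimum."""

    @lru_cache(maxsize=None)
    def go(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG_INF
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + go(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "X" else gap_open + gap_extend
            best = max(best, -cost + go(i + 1, j, "X"))
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open + gap_extend
            best = max(best, -cost + go(i, j + 1, "Y"))
        return best

    return go(0, 0, "M")


def exhaustive_accumulation(presence: np.ndarray) -> np.ndarray:
    """Expected richness at every k by averaging over all C(N, k) subsets."""
    presence = presence.astype(bool)
    n = presence.shape[0]
    out = np.empty(n)
    for k in range(1, n + 1):
        richness = [
            presence[list(subset)].any(axis=0).sum() for subset in combinations(range(n), k)
        ]
        out[k - 1] = float(np.mean(richness))
    return out


_STOPS = {"TAA", "TAG", "TGA"}


def naive_orf_scan(seq: str, min_len_nt: int) -> set[tuple[int, int, str]]:
    """Six-frame ORF set (start, end, strand; 1-based plus-strand inclusive)
    by scanning every ATG and walking to its in-frame stop, keeping the
    longest ORF per stop codon."""
    from viromedeck.seq_algorithms import reverse_complement

    length = len(seq)
    results: set[tuple[int, int, str]] = set()
    for strand, s in (("+", seq.upper()), ("-", reverse_complement(seq).upper())):
        per_stop: dict[int, int] = {}  # stop end -> earliest ATG start (0-based)
        for i in range(length - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i + 3
            while j + 3 <= length:
                if s[j : j + 3] in _STOPS:
                    end = j + 3
                    if end not in per_stop or i < per_stop[end]:
                        per_stop[end] = i
                    break
                j += 3
        for end, start in per_stop.items():
            if end - start > min_len_nt:
                if strand == "+":
                    results.add((start + 1, end, "+"))
                else:
                    results.add((length - end + 1, length - start, "-"))
    return results
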