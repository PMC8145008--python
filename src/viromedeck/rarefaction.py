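"""Sample-based taxon accumulation (rarefaction) curves.

Given a samples x taxa incidence matrix, the expected richness after
accumulating ``k`` of the ``N`` samples is, analytically,

    E[S(k)] = sum_i ( 1 - C(N - n_i, k) / C(N, k) )

where ``n_i`` is the number of samples containing taxon ``i`` and binomial
coefficients with a smaller top index are zero.  This is the classical
hypergeometric ("exact") sample-based rarefaction formula; a permutation
estimator averaging richness over random sample orderings is provided as
well, mainly because it also yields a standard-deviation band.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import CountTable

__all__ = [
    "IncidenceMatrix",
    "AccumulationCurve",
    "incidence_from_counts",
    "accumulation_exact",
    "accumulation_random",
    "plateau_check",
]


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary samples x taxa presence matrix."""

    presence: pd.DataFrame  # bool, rows = samples, columns = taxa

    def __post_init__(self) -> None:
        if self.presence.shape[0] < 1:
            raise ValueError("incidence matrix needs at least one sample")
        vals = self.presence.to_numpy()
        if vals.dtype != bool and not np.isin(vals, [0, 1]).all():
            raise ValueError("incidence entries must be binary")

    @property
    def n_samples(self) -> int:
        return self.presence.shape[0]

    def taxon_incidence(self) -> np.ndarray:
        """Number of samples containing each taxon."""
        return self.presence.to_numpy().astype(bool).sum(axis=0)


def incidence_from_counts(table: CountTable, specimens_only: bool = True) -> IncidenceMatrix:
    """Presence = count > 0, one row per (specimen) sample."""
    cols = table.specimen_ids if specimens_only else list(table.counts.columns)
    return IncidenceMatrix(presence=(table.counts[cols] > 0).T)


@dataclass(frozen=True)
class AccumulationCurve:
    """Expected richness at every accumulation size k = 1..N.

    ``sd`` is populated only by the permutation estimator (plain standard
    deviation across permutations, no finite-population correction).
    """

    k: np.ndarray
    expected_richness: np.ndarray
    sd: np.ndarray | None = None
    n_permutations: int | None = None
    seed: int | None = None
    mode: str = "exact"

    def __post_init__(self) -> None:
        if len(self.k) != len(self.expected_richness):
            raise ValueError("k and expected_richness length mismatch")
        if np.any(np.diff(self.expected_richness) < -1e-9):
            raise ValueError("expected richness must be non-decreasing in k")

    def to_frame(self) -> pd.DataFrame:
        data = {"k": self.k, "expected_richness": self.expected_richness}
        if self.sd is not None:
            data["sd"] = self.sd
        return pd.DataFrame(data)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def accumulation_exact(m: IncidenceMatrix) -> AccumulationCurve:
    """Analytical expected accumulation curve (uniform random subsets).

    For every k, the probability that a taxon present in ``n_i`` of the
    ``N`` samples is missed by a random k-subset is C(N-n_i, k)/C(N, k);
    summing the complements over taxa gives the expected richness.
    """
    n = m.n_samples
    incidence = m.taxon_incidence()
    ks = np.arange(1, n + 1)
    expected = np.empty(len(ks))
    for j, k in enumerate(ks):
        denom = comb(n, int(k))
        expected[j] = sum(1.0 - comb(n - int(ni), int(k)) / denom for ni in incidence)
    return AccumulationCurve(k=ks, expected_richness=expected, mode="exact")


def accumulation_random(m: IncidenceMatrix, n_perm: int, seed: int) -> AccumulationCurve:
    """Permutation accumulation curve: mean and sd of running richness over
    ``n_perm`` random sample orderings (seeded, reproducible).

    At k = N every ordering has seen every sample, so the mean equals the
    total observed richness exactly and the sd is 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = m.n_samples
    pres = m.presence.to_numpy().astype(bool)
    rng = np.random.default_rng(seed)
    richness = np.empty((n_perm, n))
    for p in range(n_perm):
        order = rng.permutation(n)
        seen = np.logical_or.accumulate(pres[order], axis=0)
        richness[p] = seen.sum(axis=1)
    return AccumulationCurve(
        k=np.arange(1, n + 1),
        expected_richness=richness.mean(axis=0),
        sd=richness.std(axis=0),
        n_permutations=n_perm,
        seed=seed,
        mode="random",
    )


def plateau_check(curve: AccumulationCurve, tolerance: float = 0.0) -> tuple[bool, float]:
    """Has the curve reached its asymptote?

    True iff the final increment E[S(N)] - E[S(N-1)] is at most
    ``tolerance`` (inclusive).  Returns the boolean and the increment.
    """
    if len(curve.k) < 2:
        raise ValueError("curve must have length >= 2")
    increment = float(curve.expected_richness[-1] - curve.expected_richness[-2])
    return increment <= tolerance, increment
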