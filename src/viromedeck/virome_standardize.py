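"""Standardisation of virome count tables for inter-sample comparison.

Three corrections are applied, in the order in which a survey would list
them:

1. an abundance threshold — a cell survives only if its relative abundance
   exceeds 1/10,000 reads/taxon/sample (strict), suppressing taxonomic
   binning artefacts and index-hopping noise;
2. negative-control subtraction — a taxon detected in any process blank is
   removed from every specimen where its abundance is equal or inferior to
   its maximum abundance across the blanks (inclusive), the signature of
   inter-sample contamination;
3. per-kilobase normalisation — read counts divided by the summed length of
   the taxon's contigs in kb, making abundances comparable across genomes of
   different length.

Both filters only zero cells (a taxon row is dropped only when all-zero),
so no operation ever increases a count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import CountTable

__all__ = [
    "StandardizeConfig",
    "apply_abundance_threshold",
    "subtract_control_contamination",
    "normalize_per_kb",
    "log10_matrix",
    "classified_fraction",
    "plant_equivalents",
    "standardize",
]

_LOG_COLUMNS = ["sample_id", "taxon_id", "count", "relative_abundance", "reason"]


@dataclass(frozen=True)
class StandardizeConfig:
    """Knobs of the standardisation stage.

    ``abundance_threshold`` is a relative abundance (default 1/10,000); a
    cell must exceed it strictly to survive.  ``control_comparison_basis``
    chooses whether control subtraction compares relative abundances
    (default — library depths differ between barcoded samples) or raw
    counts.  ``pseudocount_for_log`` offsets counts before log10 so that a
    zero count maps to 0.0.
    """

    abundance_threshold: float = 1e-4
    control_comparison_basis: str = "relative"
    pseudocount_for_log: float = 1.0

    def validate(self) -> None:
        if not 0.0 < self.abundance_threshold < 1.0:
            raise ValueError("abundance_threshold must lie in (0, 1)")
        if self.control_comparison_basis not in ("relative", "raw"):
            raise ValueError("control_comparison_basis must be 'relative' or 'raw'")
        if self.pseudocount_for_log <= 0:
            raise ValueError("pseudocount_for_log must be positive")


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=_LOG_COLUMNS)


def apply_abundance_threshold(
    table: CountTable, cfg: StandardizeConfig | None = None
) -> tuple[CountTable, pd.DataFrame]:
    """Zero every specimen cell whose relative abundance is not strictly
    above the threshold.

    Relative abundance is count / total_cleaned_reads of the sample (the
    full post-QC library, not just the viral fraction).  At the boundary the
    rule is strict: 1 read in a 10,000-read library is exactly 1/10,000 and
    is removed.  Control columns are left untouched so that the subsequent
    control subtraction still sees the contamination evidence.
    """
    cfg = cfg or StandardizeConfig()
    cfg.validate()
    out = table.copy()
    rel = table.relative_abundance()
    rows = []
    for s in table.specimen_ids:
        for t in table.counts.index:
            count = int(table.counts.loc[t, s])
            if count > 0 and rel.loc[t, s] <= cfg.abundance_threshold:
                out.counts.loc[t, s] = 0
                rows.append(
                    {
                        "sample_id": s,
                        "taxon_id": t,
                        "count": count,
                        "relative_abundance": float(rel.loc[t, s]),
                        "reason": "below-abundance-threshold",
                    }
                )
    return out, (pd.DataFrame(rows, columns=_LOG_COLUMNS) if rows else _empty_log())


def subtract_control_contamination(
    table: CountTable, cfg: StandardizeConfig | None = None
) -> tuple[CountTable, pd.DataFrame]:
    """Remove suspected inter-sample contamination using negative controls.

    For every taxon with a nonzero count in at least one control, compute
    its maximum abundance across controls (relative or raw per config) and
    zero the taxon in each specimen whose abundance is equal or inferior to
    that maximum (inclusive).  Taxa absent from all controls are untouched.
    """
    cfg = cfg or StandardizeConfig()
    cfg.validate()
    controls = table.control_ids
    if not controls:
        raise ValueError("count table contains no negative_control column")
    out = table.copy()
    if cfg.control_comparison_basis == "relative":
        abundance = table.relative_abundance()
    else:
        abundance = table.counts.astype(float)
    rel = table.relative_abundance()  # for the log only
    rows = []
    for t in table.counts.index:
        ctrl_counts = table.counts.loc[t, controls]
        if (ctrl_counts <= 0).all():
            continue
        ctrl_max = float(abundance.loc[t, controls].max())
        for s in table.specimen_ids:
            count = int(table.counts.loc[t, s])
            if count > 0 and float(abundance.loc[t, s]) <= ctrl_max:
                out.counts.loc[t, s] = 0
                rows.append(
                    {
                        "sample_id": s,
                        "taxon_id": t,
                        "count": count,
                        "relative_abundance": float(rel.loc[t, s]),
                        "reason": "at-or-below-control-abundance",
                    }
                )
    return out, (pd.DataFrame(rows, columns=_LOG_COLUMNS) if rows else _empty_log())


def normalize_per_kb(table: CountTable, taxa: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reads-per-kilobase matrix: count / summed contig length (kb) per taxon.

    Requires a positive ``contig_length_kb`` for every taxon carrying a
    nonzero count; a zero count is 0.0 regardless of length.
    """
    meta = taxa if taxa is not None else table.taxa
    if meta is None:
        raise ValueError("taxon metadata with contig_length_kb required")
    lengths = meta["contig_length_kb"].reindex(table.counts.index)
    nonzero = table.counts.sum(axis=1) > 0
    bad = table.counts.index[(lengths.isna() | (lengths <= 0)) & nonzero].tolist()
    if bad:
        raise ValueError(f"missing or non-positive contig_length_kb for taxa with reads: {bad}")
    out = table.counts.astype(float).div(lengths, axis=0)
    return out.fillna(0.0)


def log10_matrix(table: CountTable, cfg: StandardizeConfig | None = None) -> pd.DataFrame:
    """log10(count + pseudocount) heatmap matrix; zero maps to 0.0 with the
    default pseudocount of 1."""
    cfg = cfg or StandardizeConfig()
    cfg.validate()
    return np.log10(table.counts.astype(float) + cfg.pseudocount_for_log)


def classified_fraction(
    classified_reads: pd.Series, total_cleaned_reads: pd.Series
) -> tuple[pd.Series, dict[str, float]]:
    """Per-sample fraction of cleaned reads receiving a viral classification.

    Returns the fractions plus min/mean/max summary across samples.
    """
    classified = classified_reads.astype(float)
    totals = total_cleaned_reads.reindex(classified.index).astype(float)
    if totals.isna().any():
        raise ValueError("total_cleaned_reads missing for some samples")
    if (totals <= 0).any():
        raise ValueError("total_cleaned_reads must be positive")
    if (classified > totals).any():
        bad = classified.index[classified > totals].tolist()
        raise ValueError(f"classified reads exceed total cleaned reads for: {bad}")
    frac = classified / totals
    stats = {"min": float(frac.min()), "mean": float(frac.mean()), "max": float(frac.max())}
    return frac, stats


def plant_equivalents(n_samples: int, individuals_per_sample: int) -> int:
    """Plant-equivalent screening effort of pooled herbivore samples.

    Under the assimilation of one (sedentary) larva's virome to the virome
    of the one plant it developed on, pooling ``individuals_per_sample``
    larvae in each of ``n_samples`` samples screens their product in plant
    equivalents: e.g. 14 samples of 50+ larvae correspond to at least 700
    plants.
    """
    if n_samples < 1 or individuals_per_sample < 1:
        raise ValueError("both arguments must be >= 1")
    return int(n_samples) * int(individuals_per_sample)


def standardize(
    table: CountTable, cfg: StandardizeConfig | None = None
) -> tuple[CountTable, pd.DataFrame]:
    """Threshold then control-subtract, returning the filtered table and the
    concatenated removal log.  All relative abundances are evaluated on the
    original ``total_cleaned_reads`` denominators, so applying the pipeline
    twice equals applying it once."""
    cfg = cfg or StandardizeConfig()
    t1, log1 = apply_abundance_threshold(table, cfg)
    t2, log2 = subtract_control_contamination(t1, cfg)
    parts = [l for l in (log1, log2) if len(l)]
    log = pd.concat(parts, ignore_index=True) if parts else _empty_log()
    return t2, log
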