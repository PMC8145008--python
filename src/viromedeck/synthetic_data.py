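"""Synthetic virome experiments with planted ground truth.

This module generates the three kinds of input the pipeline consumes —
sample x taxon read-count tables, reference/pileup pairs, and forward/reverse
alignment hit tables — with a known planted truth object, so that every
downstream stage (decontamination, rarefaction, consensus calling,
reciprocal confirmation) can be tested end-to-end without any sequence
archive download.

The community model emulates a field virome survey of an insect pest and its
host plant: a handful of pooled specimen libraries (insect-dominated, with a
minority of plant samples), a few process negative controls, and virus
families of three host classes (arthropod-infecting, plant/fungus-infecting,
bacteriophage).  Abundances are lognormal — a standard skewed-community
model in which a few taxa dominate while many are rare — normalised to
proportions and allocated to reads multinomially.  Cross-contamination is
modelled as inter-sample barcode leakage: a donor taxon leaks into every
other library (negative controls included) at a fixed fraction of its donor
relative abundance before read allocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .formats_io import CountTable, HitRecord, PileupColumn

__all__ = [
    "CommunityConfig",
    "PlantedTruth",
    "simulate_community",
    "simulate_contig_and_pileup",
    "simulate_hit_tables",
    "ARTHROPOD_FAMILIES",
    "PLANT_FUNGUS_FAMILIES",
    "PHAGE_FAMILIES",
]

# Families observed in the alfalfa/weevil agrosystem, used as default taxon
# names so the synthetic tables read like the real ones.
ARTHROPOD_FAMILIES = (
    "Birnaviridae",
    "Iflaviridae",
    "Mesoniviridae",
    "Parvoviridae",
    "Permutotetraviridae",
    "Phenuiviridae",
    "Qinviridae",
    "Reoviridae",
    "Sinhaliviridae",
)
PLANT_FUNGUS_FAMILIES = (
    "Alphaflexiviridae",
    "Amalgaviridae",
    "Bromoviridae",
    "Caulimoviridae",
    "Endornaviridae",
    "Geminiviridae",
    "Luteoviridae",
    "Partitiviridae",
    "Secoviridae",
    "Solemoviridae",
    "Tymoviridae",
)
PHAGE_FAMILIES = ("Microviridae", "Myoviridae", "Siphoviridae")

_DEFAULT_FAMILY_POOL = {
    "arthropod": ARTHROPOD_FAMILIES,
    "plant_fungus": PLANT_FUNGUS_FAMILIES,
    "phage": PHAGE_FAMILIES,
}


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of a simulated virome survey.

    Defaults mirror the study design the package targets: 16 specimen
    libraries (14 insect pools plus 2 plant pools), 3 process negative
    controls, and the observed family richness per host class (9 arthropod,
    11 plant/fungus, 3 phage families).

    Parameters
    ----------
    reads_per_sample
        Viral reads allocated per specimen library.  100,000 keeps the
        multinomial structure of a MiSeq-scale virome at desk-test runtime.
    abundance_lognormal_mu, abundance_lognormal_sigma
        Parameters of the lognormal taxon-abundance distribution (natural
        log scale).  sigma = 1.5 spans roughly three orders of magnitude,
        matching the "few dominant, many rare" shape of real viromes.
    contamination_rate
        Probability that a taxon leaks out of its most abundant (donor)
        sample into all other libraries.
    contamination_intensity
        Fraction of the donor relative abundance that appears in each
        recipient *specimen* library.
    control_intensity
        Fraction of the donor relative abundance appearing in negative
        controls; ``None`` means "same as contamination_intensity".  The
        control-subtraction filter is guaranteed to catch a leak only when
        this is at least the specimen intensity.
    """

    n_specimen_samples: int = 16
    n_plant_samples: int = 2
    n_control_samples: int = 3
    n_taxa_per_host_class: Mapping[str, int] = field(
        default_factory=lambda: {"arthropod": 9, "plant_fungus": 11, "phage": 3}
    )
    reads_per_sample: int = 100_000
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 1.5
    contamination_rate: float = 0.15
    contamination_intensity: float = 0.02
    control_intensity: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if self.n_specimen_samples < 1:
            raise ValueError("need at least one specimen sample")
        if not 0 <= self.n_plant_samples <= self.n_specimen_samples:
            raise ValueError("n_plant_samples must lie in [0, n_specimen_samples]")
        if self.n_control_samples < 0:
            raise ValueError("n_control_samples must be >= 0")
        if sum(self.n_taxa_per_host_class.values()) == 0:
            raise ValueError("empty taxon set")
        if any(n < 0 for n in self.n_taxa_per_host_class.values()):
            raise ValueError("taxon counts must be >= 0")
        for name in ("contamination_rate", "contamination_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.control_intensity is not None and not 0.0 <= self.control_intensity <= 1.0:
            raise ValueError("control_intensity must lie in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators.

    Only the fields relevant to the generator that produced the object are
    populated; the rest stay at their empty defaults.
    """

    #: taxon id -> host class
    host_class: dict[str, str] = field(default_factory=dict)
    #: taxa x samples frame of {"", "resident", "contaminant"} labels
    flags: pd.DataFrame | None = None
    #: contaminating taxon -> donor sample id
    donors: dict[str, str] = field(default_factory=dict)
    #: planted substitutions: (position, ref_base, alt_base, planted_depth)
    mutations: list[tuple[int, str, str, int]] = field(default_factory=list)
    #: contig id -> True when genuinely viral (hit-table generator)
    viral_labels: dict[str, bool] = field(default_factory=dict)

    def contaminant_cells(self) -> list[tuple[str, str]]:
        """(taxon, sample) pairs where a planted contaminant landed."""
        if self.flags is None:
            return []
        out = []
        for taxon, row in self.flags.iterrows():
            for sample, flag in row.items():
                if flag == "contaminant":
                    out.append((str(taxon), str(sample)))
        return out


# ---------------------------------------------------------------------------
# Community simulation
# ---------------------------------------------------------------------------


def _taxon_names(config: CommunityConfig) -> tuple[list[str], dict[str, str]]:
    names: list[str] = []
    host_class: dict[str, str] = {}
    for cls in ("arthropod", "plant_fungus", "phage"):
        n = config.n_taxa_per_host_class.get(cls, 0)
        pool = _DEFAULT_FAMILY_POOL[cls]
        for i in range(n):
            name = pool[i] if i < len(pool) else f"{cls.capitalize()}Fam{i + 1:02d}"
            names.append(name)
            host_class[name] = cls
    return names, host_class


def simulate_community(config: CommunityConfig) -> tuple[CountTable, PlantedTruth]:
    """Draw one synthetic virome survey.

    Specimen libraries draw taxon proportions from a lognormal community and
    allocate exactly ``reads_per_sample`` reads multinomially, so every
    specimen column sums to that value.  Contaminating taxa additionally
    appear in negative controls and in non-resident specimen libraries at
    ``intensity x donor relative abundance``.  The returned
    :class:`PlantedTruth` labels every (taxon, sample) cell as resident or
    contaminant and records donor samples.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    taxa, host_class = _taxon_names(config)
    n_insect = config.n_specimen_samples - config.n_plant_samples
    insect_ids = [f"Hp{i + 1:02d}" for i in range(n_insect)]
    plant_ids = [f"Ms{i + 1:02d}" for i in range(config.n_plant_samples)]
    control_ids = [f"NC{i + 1}" for i in range(config.n_control_samples)]
    specimen_ids = insect_ids + plant_ids
    all_ids = specimen_ids + control_ids

    # Residency: insect pools can carry viruses of every host class (plant
    # viruses arrive trophically, phages with the gut microbiota); plant
    # pools carry only plant/fungus viruses.
    resident = pd.DataFrame(False, index=taxa, columns=all_ids)
    for s in insect_ids:
        resident.loc[:, s] = True
    for s in plant_ids:
        for t in taxa:
            resident.loc[t, s] = host_class[t] == "plant_fungus"

    # Lognormal abundances per resident cell, normalised per column.
    raw = pd.DataFrame(0.0, index=taxa, columns=all_ids)
    for s in specimen_ids:
        mask = resident[s].to_numpy()
        draws = rng.lognormal(
            config.abundance_lognormal_mu, config.abundance_lognormal_sigma, int(mask.sum())
        )
        col = np.zeros(len(taxa))
        col[mask] = draws
        total = col.sum()
        raw[s] = col / total if total > 0 else col

    # Pick contaminating taxa and their donors (sample of max rel abundance).
    truth_flags = pd.DataFrame("", index=taxa, columns=all_ids)
    truth_flags[resident] = "resident"
    donors: dict[str, str] = {}
    leak = pd.DataFrame(0.0, index=taxa, columns=all_ids)
    ctrl_intensity = (
        config.contamination_intensity
        if config.control_intensity is None
        else config.control_intensity
    )
    contaminating = rng.random(len(taxa)) < config.contamination_rate
    for t, is_contaminating in zip(taxa, contaminating):
        if not is_contaminating:
            continue
        donor_rel = raw.loc[t, specimen_ids]
        if donor_rel.max() <= 0:
            continue
        donor = str(donor_rel.idxmax())
        donors[t] = donor
        for s in all_ids:
            if s == donor:
                continue
            intensity = ctrl_intensity if s in control_ids else config.contamination_intensity
            leak.loc[t, s] = intensity * donor_rel.max()
            if not resident.loc[t, s]:
                truth_flags.loc[t, s] = "contaminant"

    # Allocate reads.
    counts = pd.DataFrame(0, index=taxa, columns=all_ids, dtype=int)
    for s in specimen_ids:
        p = (raw[s] + leak[s]).to_numpy()
        p = p / p.sum()
        counts[s] = rng.multinomial(config.reads_per_sample, p)
    for s in control_ids:
        p = leak[s].to_numpy()
        spill = p.sum()
        if spill <= 0:
            continue  # nothing leaked: control column stays all-zero
        # Controls are sequenced to comparable depth but contain only leaked
        # material; the non-leak mass is an absorbing "background" bucket.
        probs = np.append(p, max(0.0, 1.0 - spill))
        drawn = rng.multinomial(config.reads_per_sample, probs / probs.sum())
        counts[s] = drawn[:-1]

    samples = pd.DataFrame(
        {
            "role": ["specimen"] * len(specimen_ids) + ["negative_control"] * len(control_ids),
            "host": ["weevil"] * len(insect_ids)
            + ["alfalfa"] * len(plant_ids)
            + ["none"] * len(control_ids),
            "habitat": [
                "crop" if i % 2 == 0 else "meadow" for i in range(len(specimen_ids))
            ]
            + ["lab"] * len(control_ids),
            "total_cleaned_reads": [config.reads_per_sample] * len(all_ids),
        },
        index=pd.Index(all_ids, name="sample_id"),
    )
    taxa_meta = pd.DataFrame(
        {
            "family": taxa,
            "host_class": [host_class[t] for t in taxa],
            "contig_length_kb": np.round(rng.uniform(1.5, 12.5, len(taxa)), 3),
        },
        index=pd.Index(taxa, name="taxon_id"),
    )

    table = CountTable(counts=counts, samples=samples, taxa=taxa_meta)
    truth = PlantedTruth(host_class=host_class, flags=truth_flags, donors=donors)
    return table, truth


# ---------------------------------------------------------------------------
# Contig / pileup simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_contig_and_pileup(
    length_nt: int,
    n_mutations: int,
    depth_mean: float,
    low_depth_fraction: float,
    seed: int,
    error_rate: float = 0.01,
    depth_threshold: int = 5,
) -> tuple[str, str, list[PileupColumn], PlantedTruth]:
    """Simulate a reference contig, a mutated isolate, and its pileup.

    ``n_mutations`` substitutions are planted at distinct positions.  A
    fraction ``low_depth_fraction`` of them is given depth below
    ``depth_threshold`` (so the depth rule of the consensus caller can be
    exercised); the rest are guaranteed depth at or above it.  Sequencing
    error adds ``error_rate`` of each column's reads spread uniformly over
    the three non-consensus bases.
    """
    if length_nt < 1:
        raise ValueError("length_nt must be >= 1")
    if not 0 <= n_mutations <= length_nt:
        raise ValueError("n_mutations must lie in [0, length_nt]")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    if not 0.0 <= low_depth_fraction <= 1.0:
        raise ValueError("low_depth_fraction must lie in [0, 1]")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")

    rng = np.random.default_rng(seed)
    ref = rng.choice(_BASES, size=length_nt)
    mutated = ref.copy()

    positions = np.sort(rng.choice(length_nt, size=n_mutations, replace=False)) + 1
    n_low = int(round(low_depth_fraction * n_mutations))
    low_positions = set(rng.permutation(positions)[:n_low].tolist())

    truth = PlantedTruth()
    columns: list[PileupColumn] = []
    mutated_at: dict[int, str] = {}
    for pos in positions:
        ref_base = ref[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref_base])
        mutated[pos - 1] = alt
        mutated_at[int(pos)] = str(alt)

    for pos in range(1, length_nt + 1):
        is_mut = pos in mutated_at
        if is_mut and pos in low_positions:
            depth = int(rng.integers(1, depth_threshold))  # 1 .. threshold-1
        elif is_mut:
            depth = depth_threshold + int(rng.poisson(max(depth_mean - depth_threshold, 0.0)))
        else:
            depth = max(1, int(rng.poisson(depth_mean)))
        major = mutated_at[pos] if is_mut else str(ref[pos - 1])
        n_err = int(rng.binomial(depth, error_rate)) if error_rate > 0 else 0
        counts = {b: 0 for b in "ACGT"}
        counts["N"] = 0
        counts[major] = depth - n_err
        if n_err:
            others = [b for b in "ACGT" if b != major]
            err_alloc = rng.multinomial(n_err, [1 / 3] * 3)
            for b, n in zip(others, err_alloc):
                counts[b] += int(n)
        columns.append(PileupColumn(position=pos, ref_base=str(ref[pos - 1]), counts=counts))
        if is_mut:
            truth.mutations.append((pos, str(ref[pos - 1]), mutated_at[pos], depth))

    return "".join(ref), "".join(mutated), columns, truth


# ---------------------------------------------------------------------------
# Hit-table simulation
# ---------------------------------------------------------------------------

_VIRAL_TAXONOMY = "Viruses; Riboviria; Orthornavirae"
_CELLULAR_TAXONOMIES = (
    "Bacteria; Proteobacteria; Gammaproteobacteria",
    "Eukaryota; Arthropoda; Insecta",
    "Bacteria; Firmicutes; Bacilli",
)


def _make_hit(
    rng: np.random.Generator,
    query: str,
    subject: str,
    e_value: float,
    taxonomy: str,
) -> HitRecord:
    aln_len = int(rng.integers(150, 900))
    ident = float(np.round(rng.uniform(35.0, 95.0), 1))
    return HitRecord(
        query_id=query,
        subject_id=subject,
        percent_identity=ident,
        alignment_length=aln_len,
        mismatches=int(aln_len * (1 - ident / 100)),
        gap_opens=int(rng.integers(0, 5)),
        q_start=1,
        q_end=aln_len,
        s_start=1,
        s_end=aln_len,
        e_value=e_value,
        bit_score=float(np.round(rng.uniform(50, 800), 1)),
        subject_taxonomy=taxonomy,
    )


def simulate_hit_tables(
    n_true_viral: int, n_false_positive: int, seed: int
) -> tuple[list[HitRecord], list[HitRecord], PlantedTruth]:
    """Simulate forward (viral-database) and reverse (comprehensive-database)
    hit tables with planted non-viral false positives.

    Every contig receives a viral forward best hit below the forward cutoff
    (the forward database contains only viral subjects, so even a cellular
    contig finds a spurious viral match there).  In the reverse search,
    genuinely viral contigs hit a viral subject below the reverse cutoff,
    while false positives find their true cellular homolog as best hit.
    """
    if n_true_viral < 0 or n_false_positive < 0:
        raise ValueError("contig counts must be >= 0")
    rng = np.random.default_rng(seed)
    truth = PlantedTruth()
    forward: list[HitRecord] = []
    reverse: list[HitRecord] = []

    for i in range(n_true_viral):
        cid = f"contig_T{i + 1:02d}"
        truth.viral_labels[cid] = True
        forward.append(
            _make_hit(rng, cid, f"viral_ref_{i + 1}", 10.0 ** rng.uniform(-30, -6), _VIRAL_TAXONOMY)
        )
        best_e = 10.0 ** rng.uniform(-30, -4)
        reverse.append(_make_hit(rng, cid, f"nr_viral_{i + 1}", best_e, _VIRAL_TAXONOMY))
        # a weaker cellular hit below the best one, as real nr searches return
        reverse.append(
            _make_hit(
                rng,
                cid,
                f"nr_cell_{i + 1}",
                best_e * 10.0 ** rng.uniform(2, 6),
                str(rng.choice(_CELLULAR_TAXONOMIES)),
            )
        )

    for i in range(n_false_positive):
        cid = f"contig_F{i + 1:02d}"
        truth.viral_labels[cid] = False
        forward.append(
            _make_hit(rng, cid, f"viral_ref_fp_{i + 1}", 10.0 ** rng.uniform(-12, -6), _VIRAL_TAXONOMY)
        )
        best_e = 10.0 ** rng.uniform(-40, -10)
        reverse.append(
            _make_hit(rng, cid, f"nr_cell_fp_{i + 1}", best_e, str(rng.choice(_CELLULAR_TAXONOMIES)))
        )
        reverse.append(
            _make_hit(
                rng,
                cid,
                f"nr_viral_fp_{i + 1}",
                best_e * 10.0 ** rng.uniform(4, 8),
                _VIRAL_TAXONOMY,
            )
        )

    return forward, reverse, truth
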