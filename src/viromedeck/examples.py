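"""Worked example: the alfalfa/weevil field survey.

This module encodes, as package data, the published inputs of the survey
the pipeline was designed around — the virus family lists per host class,
the identity evidence for the 17 reconstructed contigs, and the iflavirus
screening primer pair — so the discovery arithmetic can be replayed
without any sequence download.  Identity values for individual contigs are
representative points inside the published ranges (98.2–100% nt for known
isolates, 36.6–57.2% aa for novel genomes), with both range endpoints
realised.  Template sequences built here are synthetic: only the primer
coordinates are real.
"""

from __future__ import annotations

import numpy as np

from .demarcation import ContigEvidence
from .seq_algorithms import reverse_complement
from .synthetic_data import (
    ARTHROPOD_FAMILIES,
    PHAGE_FAMILIES,
    PLANT_FUNGUS_FAMILIES,
)

__all__ = [
    "survey_family_lists",
    "survey_contig_evidence",
    "IFLAVIRUS_FWD_PRIMER",
    "IFLAVIRUS_REV_PRIMER",
    "IFLAVIRUS_FWD_START",
    "IFLAVIRUS_REV_START",
    "synthetic_pcr_template",
    "SURVEY_N_WEEVIL_SAMPLES",
    "SURVEY_MIN_LARVAE_PER_SAMPLE",
]

#: 14 pooled weevil samples, each containing at least 50 larvae.
SURVEY_N_WEEVIL_SAMPLES = 14
SURVEY_MIN_LARVAE_PER_SAMPLE = 50

#: screening primer pair for the dominant weevil iflavirus, named by the
#: 1-based 5' coordinates of the two primers on the genome (forward at
#: 8007, reverse at 9134 — a 1127 nt region of the polyprotein gene).
IFLAVIRUS_FWD_PRIMER = "GCTGGCTTTTCAGACGGCTCTA"
IFLAVIRUS_REV_PRIMER = "TGGATTACCGCTAGGCATCCCA"
IFLAVIRUS_FWD_START = 8007
IFLAVIRUS_REV_START = 9134


def survey_family_lists() -> dict[str, tuple[str, ...]]:
    """Virus families detected in the survey, by host class."""
    return {
        "arthropod": ARTHROPOD_FAMILIES,
        "plant_fungus": PLANT_FUNGUS_FAMILIES,
        "phage": PHAGE_FAMILIES,
    }


def synthetic_pcr_template(seed: int = 0, length: int = 9700) -> str:
    """A synthetic iflavirus-genome-sized template with the screening primer
    sites planted at their published coordinates (everything else random)."""
    if length < IFLAVIRUS_REV_START:
        raise ValueError(f"template must be at least {IFLAVIRUS_REV_START} nt")
    rng = np.random.default_rng(seed)
    bases = rng.choice(list("ACGT"), size=length)
    fwd = list(IFLAVIRUS_FWD_PRIMER)
    bases[IFLAVIRUS_FWD_START - 1 : IFLAVIRUS_FWD_START - 1 + len(fwd)] = fwd
    rc_rev = list(reverse_complement(IFLAVIRUS_REV_PRIMER))
    bases[IFLAVIRUS_REV_START - len(rc_rev) : IFLAVIRUS_REV_START] = rc_rev
    return "".join(bases)


def survey_contig_evidence() -> list[ContigEvidence]:
    """Identity evidence for the 17 reconstructed contigs.

    Eight contigs (the tripartite alfalfa mosaic virus plus five
    single-contig viruses) are near-identical to six already described
    plant virus species.  Nine genomes are highly divergent: three fall
    under a family demarcation criterion (one alphaflexivirus, two
    iflaviruses) and six belong to families without one (three
    sobemoviruses, one permutotetravirus, one sinaivirus, and one
    picorna-like virus unclassified at the family level).
    """
    known = [
        # Alfalfa mosaic virus: one contig per genome segment
        ("AMV_RNA1", "Bromoviridae", "Alfalfa_mosaic_virus", 99.5),
        ("AMV_RNA2", "Bromoviridae", "Alfalfa_mosaic_virus", 99.1),
        ("AMV_RNA3", "Bromoviridae", "Alfalfa_mosaic_virus", 100.0),
        ("MsAV1", "Amalgaviridae", "Medicago_sativa_amalgavirus_1", 98.2),
        ("MsAPV1", "Partitiviridae", "Medicago_sativa_alphapartitivirus_1", 99.8),
        ("MsAPV2", "Partitiviridae", "Medicago_sativa_alphapartitivirus_2", 98.9),
        ("BLRV", "Luteoviridae", "Bean_leafroll_virus", 99.3),
        ("AVF", "Tymoviridae", "Alfalfa_virus_F", 100.0),
    ]
    novel = [
        # (id, family, host_class, marker identities to closest relative)
        ("HpaAV", "Alphaflexiviridae", "plant_fungus", {"capsid": 44.0, "polymerase": 50.5}),
        ("HpaSobemo1", "Solemoviridae", "plant_fungus", {"polymerase": 52.0}),
        ("HpaSobemo2", "Solemoviridae", "plant_fungus", {"polymerase": 48.3}),
        ("HpaSobemo3", "Solemoviridae", "plant_fungus", {"polymerase": 55.0}),
        ("HpaIV1", "Iflaviridae", "arthropod", {"capsid": 51.0, "polyprotein": 46.0}),
        ("HpaIV2", "Iflaviridae", "arthropod", {"capsid": 57.2}),
        ("HpaPermutotetra", "Permutotetraviridae", "arthropod", {"capsid": 36.6}),
        ("HpaSinai", "Sinhaliviridae", "arthropod", {"polymerase": 43.5}),
        ("HpaV1", "unclassified_Picornavirales", "arthropod", {"polyprotein": 39.8}),
    ]
    evidence = [
        ContigEvidence(
            contig_id=cid,
            family=family,
            closest_relative_id=relative,
            nt_genome_identity=nt_ident,
            host_class="plant_fungus",
        )
        for cid, family, relative, nt_ident in known
    ]
    evidence += [
        ContigEvidence(
            contig_id=cid,
            family=family,
            marker_identities=markers,
            closest_relative_id=f"{cid}_closest_relative",
            host_class=host_class,
        )
        for cid, family, host_class, markers in novel
    ]
    return evidence
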