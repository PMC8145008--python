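import numpy as np
import pandas as pd
import pytest

from viromedeck.formats_io import CountTable
from viromedeck.synthetic_data import CommunityConfig, simulate_community


def make_count_table(counts: dict[str, dict[str, int]], roles: dict[str, str],
                     totals: dict[str, int] | None = None,
                     taxa_meta: pd.DataFrame | None = None) -> CountTable:
    """Build a small CountTable from nested dicts {taxon: {sample: count}}."""
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    df.index.name = "taxon_id"
    samples = pd.DataFrame(
        {
            "role": [roles[s] for s in df.columns],
            "host": ["test"] * len(df.columns),
            "habitat": ["test"] * len(df.columns),
            "total_cleaned_reads": [
                (totals or {}).get(s, int(df[s].sum())) for s in df.columns
            ],
        },
        index=pd.Index(df.columns, name="sample_id"),
    )
    return CountTable(counts=df, samples=samples, taxa=taxa_meta)


@pytest.fixture(scope="session")
def small_community():
    """A reproducible community where controls see leaks at full donor
    intensity while specimens receive a 50x weaker spill."""
    cfg = CommunityConfig(
        n_specimen_samples=8,
        n_plant_samples=2,
        n_control_samples=3,
        n_taxa_per_host_class={"arthropod": 6, "plant_fungus": 7, "phage": 2},
        reads_per_sample=100_000,
        contamination_rate=0.4,
        contamination_intensity=0.02,
        control_intensity=1.0,
        seed=11,
    )
    return simulate_community(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
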