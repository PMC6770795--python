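import pandas as pd
import pytest

from harmonics import InteractionReference, SyntheticConfig


@pytest.fixture
def tiny_assignment() -> pd.DataFrame:
    """Six genes on three chromosomes: {g1,g2 | g3,g4,g5 | g6}."""
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5", "g6"],
            "species": "species1",
            "chromosome": ["c1", "c1", "c2", "c2", "c2", "c3"],
            "period_class": "P8",
        }
    )


@pytest.fixture
def path_ref() -> InteractionReference:
    """The path graph a–b–c–d."""
    return InteractionReference.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        seed=11,
        n_chromosomes_per_species=6,
        genes_per_chromosome=20,
        set_sizes={"P8": 15, "P12": 25, "P24": 50},
        ppi_n_nodes=80,
        ncrg_size=8,
        energy_n_per_group={"P8": 20, "P12": 30, "P24": 40, "NONOSC": 25},
    )
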