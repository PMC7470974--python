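import numpy as np
import pandas as pd
import pytest

from promoterome.synthetic_data import SimConfig, simulate_dataset


SMALL_RECIPE = {"canonical_down": 4, "alternative_down": 4, "canonical_up": 4,
                "alternative_up": 4, "discarded": 4, "not_candidate": 10,
                "not_selected": 10}


def small_config(seed: int = 11, n_genes: int = 400) -> SimConfig:
    return SimConfig(
        seed=seed, n_genes=n_genes, genes_per_chrom=200,
        n_up_a=40, n_up_b=40, alt_recipe=dict(SMALL_RECIPE),
        n_temporal_gained=30, n_temporal_lost=15, n_temporal_none=60)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest ground-truthed dataset shared by the unit tests."""
    return simulate_dataset(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_ctss():
    return pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr1", "chr2"],
        "pos": [100, 140, 150, 7],
        "strand": ["+", "+", "-", "+"],
        "count": [5, 3, 2, 1],
    })
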