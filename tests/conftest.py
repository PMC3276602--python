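import numpy as np
import pytest

from aimsel import (
    FrequencyTable,
    SimConfig,
    generate_ancestral_freqs,
    score_table,
    simulate_admixed,
)


@pytest.fixture
def toy_table() -> FrequencyTable:
    """Three markers spanning the informativeness range on one chromosome."""
    return FrequencyTable.from_arrays(
        marker_id=["A", "B", "C"],
        chrom=["1", "1", "1"],
        pos=[100_000, 300_000, 500_000],
        freqs={"pop1": [1.0, 0.7, 0.5], "pop2": [0.0, 0.2, 0.5]},
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but realistic simulated study shared across test modules."""
    config = SimConfig(
        n_markers=3000,
        chrom_lengths=(10_000_000,) * 4,
        fst=0.15,
        m0=0.7,
        generations=10,
        n_admixed=60,
        n_founders=120,
        seed=42,
    )
    table = generate_ancestral_freqs(config)
    G, truth = simulate_admixed(table, config)
    scores = score_table(table)
    return config, table, scores, G, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
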