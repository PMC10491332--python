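import numpy as np
import pytest

from pepregex.peptide_data import Dataset, PeptideRecord
from pepregex.synthetic import SyntheticSpec, make_synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20230901)


@pytest.fixture
def toy_dataset():
    """Six hand-made peptides spanning both CEST classes."""
    return Dataset(
        [
            PeptideRecord("KKKKKKKKKKKK", 12.5),
            PeptideRecord("APVPKKPRLL", 9.0),
            PeptideRecord("KWRAAAAAAAAA", 18.46),
            PeptideRecord("AAKWRSSTTQQA", 16.08),
            PeptideRecord("TTTTEEEDDD", 4.2),
            PeptideRecord("QSLKQSIKKLKK", 15.0),
        ],
        name="toy",
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """Noise-free planted-motif data (default generator conditions with
    the noise switched off) used by the end-to-end evolution checks."""
    spec = SyntheticSpec(n_peptides=150, noise_sd=0.0, seed=11)
    ds, truth = make_synthetic_dataset(spec)
    return ds, truth


@pytest.fixture(scope="session")
def capped_dataset():
    """Noise-free data where no planted motif occurs twice in a sequence,
    so presence-based scoring is exactly linear in CEST — the fixture for
    the exact-correlation oracle."""
    spec = SyntheticSpec(
        n_peptides=150, noise_sd=0.0, seed=11, max_motif_occurrences=1
    )
    ds, truth = make_synthetic_dataset(spec)
    return ds, truth


@pytest.fixture(scope="session")
def paired_runs(planted_dataset):
    """Ten paired (trained, random-weights) scaled evolution runs on the
    noise-free planted-motif data; shared across the elitism, ablation
    and end-to-end tests to keep the suite fast."""
    from pepregex.gp_engine import EvolutionConfig, run_evolution

    ds, _truth = planted_dataset
    pairs = []
    for seed in range(10):
        trained = run_evolution(
            EvolutionConfig(population_size=100, generations=30, seed=seed), ds
        )
        random_mode = run_evolution(
            EvolutionConfig(
                population_size=100,
                generations=30,
                seed=seed,
                mode="random_weights",
            ),
            ds,
        )
        pairs.append((trained, random_mode))
    return pairs
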