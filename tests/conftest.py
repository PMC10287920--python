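import numpy as np
import pytest

from snapcluster import (
    MultimodalDataset,
    ScheduleConfig,
    SyntheticSpec,
    VAEConfig,
    generate,
    preprocess_dataset,
    train_snapshot_ensemble,
)


@pytest.fixture(scope="session")
def small_dataset() -> MultimodalDataset:
    """Separable 2-modality dataset (120 cells, 3 types), z-scored."""
    spec = SyntheticSpec(
        n_cells=120,
        k=3,
        modality_dims={"rna": 60, "adt": 12},
        separation=4.0,
        informative_fraction=0.3,
        seed=11,
    )
    ds, _ = preprocess_dataset(generate(spec), min_prevalence=None, min_cells_per_type=None)
    return ds


@pytest.fixture(scope="session")
def tiny_vae_config(small_dataset) -> VAEConfig:
    return VAEConfig.for_dataset(small_dataset, latent_dim=8)


@pytest.fixture(scope="session")
def trained_ensemble(small_dataset, tiny_vae_config):
    """A 5-cycle snapshot ensemble on the small dataset (shared across tests)."""
    sched = ScheduleConfig(n_cycles=5, batch_size=32)
    return train_snapshot_ensemble(small_dataset, tiny_vae_config, sched, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
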