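"""Shared fixtures: small synthetic datasets and trained models.

Everything is generated programmatically from fixed seeds so the suite
needs no data files; session scope keeps the trained models reusable
across test modules.
"""

import numpy as np
import pytest

import desvisc as dv


@pytest.fixture(scope="session")
def small_config() -> dv.GeneratorConfig:
    # compact study: ~200 records, 14 systems, default noise
    return dv.GeneratorConfig(
        seed=42,
        n_pure_systems=6,
        n_cosolvent_systems=8,
        cosolvent_fractions=(0.2, 0.5, 0.8),
        deep_dilution_every=4,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    dataset, law = dv.gen_viscosity_dataset(small_config)
    dv.split_dataset(dataset, seed=42)
    return dataset, law


@pytest.fixture(scope="session")
def small_model(small_dataset):
    dataset, _ = small_dataset
    cfg = dv.TrainingConfig(seed=0, max_iterations=200)
    return dv.train(dataset, (9, 8, 1), cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
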