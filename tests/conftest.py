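"""Shared fixtures: fixture molecules, configs, and one trained toy model.

The toy model is trained once per session (a couple of minutes on one CPU)
and shared by every test that needs a converged translator.
"""

import numpy as np
import pytest

import ms2mol as m

FIXTURE_SEED = 7
N_FIXTURES = 50


@pytest.fixture(scope="session")
def frag_config():
    # min_fragment_mass 0 so that even the smallest fixtures fragment richly
    return m.FragmentationConfig(min_fragment_mass=0.0)


@pytest.fixture(scope="session")
def fixture_molecules():
    return m.generate_fixture_molecules(N_FIXTURES, FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_dataset(fixture_molecules, frag_config):
    return m.build_dataset(fixture_molecules, frag_config)


@pytest.fixture(scope="session")
def trained_toy_model(fixture_dataset):
    """A width-64, 2+2-layer model overfitted on the 50 fixture molecules."""
    config = m.toy_model_config()
    model = m.build_model(config, seed=1)
    train_config = m.TrainConfig(
        batch_size=32,
        base_batch_size=32,
        model_width=config.model_width,
        warmup_steps=300,
        patience=200,
        max_epochs=200,
        seed=3,
    )
    checkpoint = m.train(model, fixture_dataset, fixture_dataset, train_config)
    return model, checkpoint
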