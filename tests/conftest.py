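"""Shared fixtures: a small synthetic session reused by pipeline-level tests."""

import numpy as np
import pytest

from spikespeech import pipeline, synth


@pytest.fixture(scope="session")
def small_session():
    """A compact session (8 channels, 3 tokens x 8 reps) for pipeline tests."""
    spec = synth.SessionSpec(reps_per_token=8, seed=11)
    model = synth.sample_encoding_model(n_channels=8, seed=11)
    bundle, trials, model = synth.make_session(spec, model)
    return bundle, trials, model


@pytest.fixture(scope="session")
def small_dataset(small_session):
    bundle, trials, _ = small_session
    return pipeline.assemble_dataset(bundle, trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
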