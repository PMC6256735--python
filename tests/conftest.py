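"""Shared fixtures: small synthetic sessions and a desk-scale trained model.

Everything is generated programmatically; fixture sizes are kept small so
the whole suite runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

import nsca


@pytest.fixture(scope="session")
def small_session() -> nsca.EpochSet:
    """6 epochs/class, 22 channels, full 4 s window (seed 0)."""
    return nsca.generate_session(nsca.SimParams(seed=0, epochs_per_class=6))


@pytest.fixture(scope="session")
def small_features(small_session) -> nsca.FeatureMatrix:
    return nsca.extract_features(small_session, nsca.MfccParams(), "both")


@pytest.fixture(scope="session")
def fast_config() -> nsca.PipelineConfig:
    """Reduced SAE epochs / GA budget for quick end-to-end checks."""
    return nsca.PipelineConfig(sae_epochs=60, generations=12,
                               population_size=20, n_detectors=4)


@pytest.fixture(scope="session")
def small_model(small_features, fast_config) -> nsca.NscaModel:
    return nsca.train(small_features, fast_config, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
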