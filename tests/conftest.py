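import numpy as np
import pytest

import nirsnet as nn

FS = 7.8125


@pytest.fixture(scope="session")
def montage():
    return nn.default_montage()


@pytest.fixture(scope="session")
def design():
    return nn.default_design(FS)


@pytest.fixture(scope="session")
def kernel():
    return nn.canonical_hrf(FS)


@pytest.fixture(scope="session")
def design_matrix(design, kernel):
    return nn.build_design(design, FS, design.n_samples, 128.0, kernel)


@pytest.fixture(scope="session")
def optics(montage):
    return nn.OpticsParams(separations_cm=montage.separations_cm)


@pytest.fixture(scope="session")
def quiet_spec():
    """Noise-free effect spec: pure deterministic activation on channel 10."""
    import dataclasses
    return dataclasses.replace(
        nn.EffectSpec(), innovation_sd=0.0, physio=(), drift_slope=0.0,
        spike_rate_per_min=0.0, deoxy_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def simulated_subject(montage, design):
    """One default-spec recording, shared across read-only tests."""
    return nn.simulate_subject(montage, design, nn.EffectSpec(), seed=11)
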