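import numpy as np
import pytest
from dataclasses import replace

from phycoflux.synth import make_default_truth


@pytest.fixture
def summer_truth():
    """Summer 400T ground truth with all noise switched off."""
    return replace(make_default_truth("summer", "400T"),
                   sigma_O2=0.0, sigma_AT=0.0, sigma_pH=0.0,
                   rate_noise_frac=0.0, jitter_cv=0.0)


@pytest.fixture
def winter_truth():
    return replace(make_default_truth("winter", "700T"),
                   sigma_O2=0.0, sigma_AT=0.0, sigma_pH=0.0,
                   rate_noise_frac=0.0, jitter_cv=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
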