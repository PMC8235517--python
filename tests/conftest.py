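import numpy as np
import pytest

from ctperf import GROUP_PROTOCOLS, TransportFunctionParams, build_phantom
from ctperf.phantom import default_aif


@pytest.fixture(scope="session")
def group_a():
    return GROUP_PROTOCOLS["A"]


@pytest.fixture(scope="session")
def aif_a(group_a):
    """Analytic arterial input on the 50-frame, 1 s group-A grid."""
    return default_aif(group_a)


@pytest.fixture(scope="session")
def gm_params():
    """Normal gray-matter truth: Ft = 0.01, MTT = 2 + 1·(1+1) = 4 s."""
    return TransportFunctionParams(ft=0.01, t1=2.0, sigma1=1.0, a1=1.0)


@pytest.fixture(scope="session")
def clean_phantom(group_a):
    """Small noise-free phantom with the default four-region layout."""
    return build_phantom(group_a, baseline_noise_sd=0.0, shape=(32, 32, 2), seed=0)


@pytest.fixture(scope="session")
def noisy_phantom(group_a):
    """Small phantom at the group-A baseline noise level (7.81 HU)."""
    return build_phantom(group_a, baseline_noise_sd=7.81, shape=(24, 24, 2), seed=11)
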