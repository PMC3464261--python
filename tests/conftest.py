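import numpy as np
import pytest

from relaxkit import (
    AcquisitionScheme,
    SpinSystemConstants,
    generate_dataset,
    generate_profile,
    generate_toy_structure,
    synthetic_four_helix_bundle,
)


@pytest.fixture(scope="session")
def consts():
    return SpinSystemConstants()


@pytest.fixture(scope="session")
def scheme():
    return AcquisitionScheme()


@pytest.fixture(scope="session")
def r1_delays(scheme):
    return np.array(scheme.expanded_delays("r1"))


@pytest.fixture(scope="session")
def profile_114():
    return generate_profile(114, seed=1)


@pytest.fixture(scope="session")
def noiseless_dataset(profile_114):
    scheme = AcquisitionScheme(noise_sigma=0.0)
    return generate_dataset(list(profile_114), tau_m=7.9, scheme=scheme, seed=5)


@pytest.fixture(scope="session")
def toy_helix_30():
    return generate_toy_structure("A" * 30, "helix")


@pytest.fixture(scope="session")
def bundle():
    return synthetic_four_helix_bundle()
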