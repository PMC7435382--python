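import numpy as np
import pytest

from barospiro.conditioning import ConditioningConfig
from barospiro.synth import SensorSpec, SubjectProfile, make_cohort, simulate_session


@pytest.fixture(scope="session")
def profile():
    return SubjectProfile()


@pytest.fixture(scope="session")
def noisy_sessions():
    """Three grade-A subjects with default (realistic) settings."""
    return simulate_session(make_cohort(3, 11), SensorSpec.grade_a(), seed=11)


@pytest.fixture(scope="session")
def exact_sessions():
    """Noise-free sessions on which the whole chain is exact: ideal sensors,
    no reference noise/offset, reference sampled at the barometer rate."""
    return simulate_session(
        make_cohort(3, 5),
        SensorSpec.ideal(),
        seed=5,
        reference_rate=100.0,
        reference_noise_sd=0.0,
        reference_offset=0.0,
    )


@pytest.fixture(scope="session")
def exact_conditioning():
    """Conditioning variant that is exact on noise-free aligned data:
    smoothing and downsampling disabled."""
    return ConditioningConfig(kernel=1, downsample=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
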