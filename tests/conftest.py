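import numpy as np
import pytest

from mcifkit import (
    DEFAULT_FRAMING,
    DEFAULT_SAMPLE_TIMES,
    FengInput,
    NoiseConfig,
    build_frame_schedule,
    generate_truth,
    simulate_study,
)


@pytest.fixture(scope="session")
def schedule23():
    """The 23-frame / 60-min acquisition schedule."""
    return build_frame_schedule(DEFAULT_FRAMING)


@pytest.fixture(scope="session")
def sample_times():
    return np.asarray(DEFAULT_SAMPLE_TIMES)


@pytest.fixture(scope="session")
def feng():
    """A representative bolus-shaped arterial input."""
    return FengInput(A1=100.0, A2=1.0, A3=0.5, lam1=4.0, lam2=0.5, lam3=0.01, tau=0.2)


@pytest.fixture(scope="session")
def truth():
    """One digital rat's ground-truth parameter set."""
    return generate_truth(7)


@pytest.fixture(scope="session")
def clean_study(truth):
    """Noiseless simulated study data for the ground-truth rat."""
    return simulate_study(truth, noise=NoiseConfig(sigma0=0.0, sample_cv=0.0))
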