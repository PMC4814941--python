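import numpy as np
import pytest

from pulsedx.cohort import SyntheticCohortSpec, generate_recording


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, wander-free generating conditions (exact waveforms)."""
    return SyntheticCohortSpec(n_healthy=2, n_fld=2, n_cirrhosis=0,
                               noise_sd=0.0, wander_amp=0.0, seed=7)


@pytest.fixture(scope="session")
def default_recording():
    """One healthy subject under the default generating conditions."""
    spec = SyntheticCohortSpec(seed=3)
    return generate_recording(spec, "healthy", "H001")


@pytest.fixture(scope="session")
def clean_recording(clean_spec):
    rec, truth = generate_recording(clean_spec, "healthy", "H001")
    return rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
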