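import numpy as np
import pytest
from hypothesis import settings

import imuwrist as iw

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def noiseless():
    return iw.SensorNoiseModel.noiseless()


@pytest.fixture(scope="session")
def stop_sign_profile():
    """10 s noise-free stop-sign trajectory to 70 deg at 35 deg/s peak rate."""
    return iw.generate_stop_sign_profile(duration=10, peak_angle=70, speed=35)


@pytest.fixture(scope="session")
def clean_trial(stop_sign_profile, noiseless):
    """Noise-free recording of the reference stop-sign profile."""
    return iw.synthesize_recording(stop_sign_profile, noise=noiseless, seed=0)


@pytest.fixture(scope="session")
def long_clean_trial(noiseless):
    """Noise-free trial with a 6 s static lead-in, long enough for drift windows."""
    profile = iw.generate_stop_sign_profile(
        duration=15, peak_angle=70, speed=35, lead_in=6.0
    )
    return iw.synthesize_recording(profile, noise=noiseless, seed=0), profile


@pytest.fixture(scope="session")
def small_cohort_dataset():
    """Features of a small default-contrast cohort (12 impaired / 12 typical)."""
    trials = iw.generate_cohort(iw.CohortSpec(n_cp=12, n_typical=12, seed=7))
    trimmed = [iw.trim_startup(t, 1.0) for t in trials]
    return iw.build_dataset(trimmed)
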