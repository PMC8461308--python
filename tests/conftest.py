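import numpy as np
import pytest

from tremorkit.synthetic import PatientProfile, SessionConfig, simulate_session


@pytest.fixture
def clean_profile():
    """Noise-free patient with integer-cycle tremor frequencies (exact RMS)."""
    return PatientProfile(
        patient_id="Pclean",
        tremor_freq=np.array([5.0, 4.0, 6.0]),
        baseline_rms=np.array([10.0, 14.0, 6.0]),
        response_threshold=5.0,
        suppression_floor=0.2,
        reset_hold=60.0,
        reemergence_ramp=20.0,
        noise_sd=0.0,
    )


@pytest.fixture
def noisy_profile(clean_profile):
    from dataclasses import replace

    return replace(clean_profile, patient_id="Pnoisy", noise_sd=1.0)


@pytest.fixture
def short_session():
    """Small but valid session: 60 s baseline (>= 30 windows), bounded tail."""
    return SessionConfig(
        before_duration=60.0,
        max_during_duration=300.0,
        after_duration=240.0,
        seed=11,
    )


@pytest.fixture
def clean_stream(clean_profile, short_session):
    return simulate_session(clean_profile, short_session)
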