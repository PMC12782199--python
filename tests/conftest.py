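import numpy as np
import pytest

from ssvepipe.experiments import reduced_protocol
from ssvepipe.protocol import ProtocolConfig
from ssvepipe.simulate import EffectSpec, EyeState, make_montage, make_topography


@pytest.fixture(scope="session")
def protocol() -> ProtocolConfig:
    """Full default protocol: 12 bins × 1.1 s at 500 Hz, 128 channels."""
    return ProtocolConfig()


@pytest.fixture(scope="session")
def small_protocol() -> ProtocolConfig:
    """Short 16-channel protocol used by the Monte-Carlo experiments."""
    return reduced_protocol()


@pytest.fixture(scope="session")
def montage16():
    return make_montage(16, seed=42)


@pytest.fixture(scope="session")
def montage128():
    return make_montage(128, seed=42)


@pytest.fixture
def control_state():
    return EyeState("S1", "control", "OD", amp_factor=1.0, phase_offset=0.0)


@pytest.fixture
def quiet_effect():
    """No noise, no artifacts, no group effect: planted signal only."""
    return EffectSpec(
        noise_scale_uv=0.0,
        patient_amp_scale_on=1.0,
        patient_amp_scale_off=1.0,
        patient_phase_delay_on=0.0,
        patient_phase_delay_off=0.0,
        amp_sigma=0.0,
        phase_sigma=0.0,
    )
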