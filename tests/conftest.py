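import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kvsim as kv

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

GROUP_PRESETS = ("kto_wt", "kto_ko", "kslow_wt", "kslow_ko")
ALL_PRESETS = kv.PRESET_NAMES


@pytest.fixture(scope="session")
def presets():
    return {name: kv.load_preset(name) for name in ALL_PRESETS}


@pytest.fixture(scope="session")
def step50_traces(presets):
    """Simulated traces at the +50 mV step for every preset (default clamp)."""
    proto = kv.ClampProtocol(v_steps=(50.0,))
    return {
        name: kv.simulate_current(None, p, proto)[0] for name, p in presets.items()
    }


@pytest.fixture(scope="session")
def planted_targets(step50_traces):
    """Feature targets forward-simulated from the group presets at +50 mV."""
    out = {}
    for name in GROUP_PRESETS:
        A, tau = kv.extract_calibration_features(step50_traces[name])
        kind = "Kto" if name.startswith("kto") else "Kslow"
        out[name] = kv.CalibrationTarget(A, tau, kind)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
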