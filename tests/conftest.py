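import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from meamod import ElectrodeMap, SpikeTrainSet, SynthConfig, generate_recording, make_electrode_map

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_recording():
    """One type-1-like synthetic recording with its ground truth and map."""
    cfg = SynthConfig(seed=11)
    sts, gt = generate_recording(cfg)
    return cfg, sts, gt, make_electrode_map(cfg)


@pytest.fixture
def small_map():
    return ElectrodeMap({"a": "source", "b": "source", "c": "target", "d": "target"})


@pytest.fixture
def two_electrode_trains():
    """Deterministic trains: j echoes i at exactly 4.5 ms."""
    ti = np.arange(1.0, 101.0)  # 100 reference spikes
    tj = ti + 0.0045
    sts = SpikeTrainSet({"i": ti, "j": tj}, duration_s=120.0)
    return sts
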