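import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from dcnpatch import SpikeRaster, constant, generate_ensemble, sinusoid


@pytest.fixture
def step_cycle_profile():
    """Sinusoid spanning 50-250 Hz over a 200 ms cycle (a step cycle)."""
    return sinusoid(amplitude_hz=100.0, baseline_hz=150.0, wavelength_ms=200.0)


@pytest.fixture
def small_raster():
    """Hand-built 2-cell raster with known spike placement (dt = 0.05 ms)."""
    spikes = np.zeros((2, 40), dtype=np.uint8)
    spikes[0, [0, 25]] = 1   # bin 0 and bin 1 (1 ms bins = 20 steps)
    spikes[1, [3, 30]] = 1
    return SpikeRaster(spikes, dt=0.05)


@pytest.fixture
def constant_raster():
    """40 cells at 200 Hz for 200 ms, default 1 ms refractory."""
    return generate_ensemble(constant(200.0), 40, 200.0, seed=11)
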