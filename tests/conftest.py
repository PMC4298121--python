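import numpy as np
import pytest

from vascmark.synthetic import WaveformParams


@pytest.fixture
def default_waveform() -> WaveformParams:
    return WaveformParams()


@pytest.fixture
def crisp_waveform() -> WaveformParams:
    """Waveform whose decay fully returns to baseline well before the
    diastolic window, so onset estimates are exact to float precision."""
    return WaveformParams(decay_time_constant=15.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def regular_polygon(radius: float, n: int = 256, center=(0.0, 0.0)) -> np.ndarray:
    ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )
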