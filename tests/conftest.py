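import numpy as np
import pytest

from ephys_batch.containers import Recording
from ephys_batch.synthetic import SimulationSpec, simulate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_recording():
    """Short artifact-free synthetic session (MEG + ECG + EOG channels)."""
    spec = SimulationSpec(duration=40.0, n_events=20, seed=11)
    rec, events, truth = simulate_recording(spec)
    return rec, events, truth


@pytest.fixture
def noise_recording(rng):
    """Pure i.i.d. noise recording, 16 MEG channels, 60 s at 100 Hz."""
    n_ch, sfreq, dur = 16, 100.0, 60.0
    data = rng.standard_normal((n_ch, int(sfreq * dur)))
    return Recording(
        data=data,
        sfreq=sfreq,
        channel_labels=[f"MEG{i:03d}" for i in range(n_ch)],
        channel_types=["meg"] * n_ch,
    )
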