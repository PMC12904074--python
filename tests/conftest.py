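import numpy as np
import pytest

from oscibar.core import EventTable, Recording, SpikeUnit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_recording():
    """One-region 10-s recording holding a unit 8 Hz cosine at 1000 Hz."""
    fs = 1000.0
    t = np.arange(0, 10, 1 / fs)
    return Recording(
        subject_id="tone", group="control", regions=["OB"],
        lfp=np.cos(2 * np.pi * 8.0 * t)[None, :], fs_hz=fs,
    )


@pytest.fixture
def small_recording(rng):
    """Two-region noise recording with one spiking unit."""
    fs = 1000.0
    lfp = rng.standard_normal((2, 5000))
    spikes = np.sort(rng.uniform(0, 5, 40))
    spikes = np.unique(spikes)
    return Recording(
        subject_id="s1", group="lesion", regions=["OB", "LEC"], lfp=lfp,
        fs_hz=fs, units=[SpikeUnit("u0", "OB", spikes)],
    )


@pytest.fixture
def simple_events():
    return EventTable.from_rows([
        dict(epoch_id="n0", label="expl", start_s=0.5, end_s=1.5, condition="novel"),
        dict(epoch_id="f0", label="expl", start_s=2.0, end_s=3.0, condition="familiar"),
        dict(epoch_id="n1", label="expl", start_s=3.5, end_s=4.5, condition="novel"),
    ])
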