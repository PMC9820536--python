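import numpy as np
import pytest

from emgait import ChannelLabel, EmgRecording, Envelope


@pytest.fixture
def four_channel_recording() -> EmgRecording:
    """1 s, 2 kHz, 4 channels of small deterministic signal."""
    rng = np.random.default_rng(42)
    return EmgRecording(
        animal_id="rat-01",
        group="TTx2EB",
        condition="pre_drug",
        sampling_rate=2000.0,
        channels=[ChannelLabel.parse(c) for c in ("Sol-L", "Sol-R", "TA-L", "TA-R")],
        signal=0.1 * rng.standard_normal((2000, 4)),
    )


def square_envelope(
    n_bursts: int = 10,
    period_s: float = 1.0,
    burst_s: float = 0.3,
    amp: float = 4.0,
    baseline: float = 0.0,
    bin_s: float = 0.005,
    start_s: float = 0.2,
) -> tuple[Envelope, np.ndarray]:
    """Noise-free rectangular burst envelope with known onsets."""
    duration = start_s + n_bursts * period_s
    n = int(round(duration / bin_s))
    values = np.full(n, baseline)
    onsets = start_s + period_s * np.arange(n_bursts)
    for onset in onsets:
        i0 = int(round(onset / bin_s))
        i1 = int(round((onset + burst_s) / bin_s))
        values[i0:i1] = amp
    env = Envelope(
        source_channel=ChannelLabel.parse("Sol-L"),
        bin_width=bin_s,
        values=values,
    )
    return env, onsets
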