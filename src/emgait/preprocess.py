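"""Raw EMG to rectified-integrated envelope.

The analysis chain is: band-pass filter (default 100-999 Hz at 2 kHz
sampling), full-wave rectification, then integration into non-overlapping
bins whose value is the mean rectified amplitude in the bin.  Two integration
presets are conventional: 5 ms bins for burst onset/offset marking and 50 ms
(20 Hz) bins for burst amplitude extraction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .io import ChannelLabel, EmgRecording, _as_label

#: Integration presets (seconds): burst marking and amplitude analysis.
BURST_BIN_S = 0.005
AMPLITUDE_BIN_S = 0.050

# Keep the upper band edge strictly below Nyquist so the filter stays stable.
_NYQUIST_MARGIN = 0.99


@dataclass
class Envelope:
    """A rectified-integrated EMG envelope for one channel.

    ``values[i]`` is the mean rectified amplitude in the i-th bin of width
    ``bin_width`` seconds starting at ``t0 + i * bin_width``; the tail of the
    signal that does not fill a whole bin is dropped.
    """

    source_channel: ChannelLabel
    bin_width: float
    values: np.ndarray
    t0: float = 0.0
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.bin_width > 0):
            raise ParameterError("bin_width must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("envelope values must be one-dimensional")
        if np.any(self.values < 0):
            raise ParameterError("envelope values must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def bin_starts(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_bins) * self.bin_width

    def time_to_bin(self, t: float) -> int:
        return int(np.floor((t - self.t0) / self.bin_width))


def bandpass(
    rec: EmgRecording,
    low: float = 100.0,
    high: float = 999.0,
    order: int = 4,
) -> EmgRecording:
    """Zero-phase Butterworth band-pass of every channel.

    ``high`` is clamped just below Nyquist; the filter is applied
    forward-backward (``sosfiltfilt``) so burst onsets are not delayed.
    Output length equals input length and the DC component is rejected.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0 < low):
        raise ParameterError(f"low cutoff must be > 0, got {low}")
    high = min(high, _NYQUIST_MARGIN * nyq)
    if not (low < high):
        raise ParameterError(
            f"band is empty after clamping: low={low} Hz, high={high} Hz (Nyquist {nyq} Hz)"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=0)
    out = rec.with_signal(filtered)
    out.meta = {**rec.meta, "filter": {"low_hz": low, "high_hz": high, "order": order, "zero_phase": True}}
    return out


def rectify(rec: EmgRecording) -> EmgRecording:
    """Full-wave rectification: every sample replaced by its absolute value."""
    return rec.with_signal(np.abs(rec.signal))


def integrate(
    rec: EmgRecording,
    channel: "ChannelLabel | str",
    window: float = BURST_BIN_S,
) -> Envelope:
    """Integrate the rectified signal of one channel into ``window``-second bins.

    Bin value = mean of the rectified samples falling in the bin; the number
    of bins is floor(duration / window) and the trailing partial bin is
    discarded.  The input need not be pre-rectified; rectification is applied
    here so ``integrate`` is safe on raw or filtered signals.
    """
    if window < 1.0 / rec.sampling_rate:
        raise ParameterError(
            f"integration window {window}s is shorter than one sample "
            f"({1.0 / rec.sampling_rate}s)"
        )
    label = _as_label(channel)
    x = np.abs(rec.channel_signal(label))
    samples_per_bin = int(round(window * rec.sampling_rate))
    if samples_per_bin < 1:
        raise ParameterError("integration window shorter than one sample")
    n_bins = x.size // samples_per_bin
    trimmed = x[: n_bins * samples_per_bin]
    values = trimmed.reshape(n_bins, samples_per_bin).mean(axis=1)
    provenance = {
        "rectified": True,
        "integration_window_s": window,
        "samples_per_bin": samples_per_bin,
    }
    if "filter" in rec.meta:
        provenance["filter"] = rec.meta["filter"]
    return Envelope(
        source_channel=label,
        bin_width=samples_per_bin / rec.sampling_rate,
        values=values,
        t0=rec.t0,
        provenance=provenance,
    )


def make_envelope(
    rec: EmgRecording,
    channel: "ChannelLabel | str",
    window: float = BURST_BIN_S,
    band: "tuple[float, float] | None" = (100.0, 999.0),
    order: int = 4,
) -> Envelope:
    """Convenience: optional band-pass, then rectified-integrated envelope."""
    if band is not None:
        rec = bandpass(rec, band[0], band[1], order=order)
    return integrate(rec, channel, window=window)
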