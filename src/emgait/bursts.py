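"""Burst detection on the envelope and episode selection.

Bursts are marked with a deterministic dual-threshold (hysteresis) detector:
baseline b = 20th percentile of the envelope, spread s = median absolute
deviation; a burst opens when the envelope reaches b + k_on*s and closes when
it falls below b + k_off*s.  Candidate bursts shorter than ``min_burst`` are
discarded, then bursts separated by gaps shorter than ``min_gap`` are merged.

Episodes of analyzable activity follow the convention of at least 10
consecutive rhythmic bursts, or no less than 10 s of irregular activity.
"Rhythmic" is operationalised as a run whose cycle-duration coefficient of
variation is at most ``max_cycle_cv`` (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ParameterError
from .io import ChannelLabel
from .preprocess import Envelope


@dataclass
class Burst:
    """One EMG burst: onset/offset times (s) and envelope peak."""

    onset: float
    offset: float
    peak_amplitude: float
    peak_time: float

    def __post_init__(self) -> None:
        if not (self.onset < self.offset):
            raise ParameterError(f"burst onset {self.onset} must precede offset {self.offset}")
        if not (self.onset <= self.peak_time <= self.offset):
            raise ParameterError("peak_time must lie within [onset, offset]")
        if not (self.peak_amplitude > 0):
            raise ParameterError("peak_amplitude must be > 0")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class BurstTrain:
    """Time-ordered, non-overlapping bursts of one channel."""

    channel: ChannelLabel
    bursts: list[Burst]
    detection_params: dict[str, Any] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [b.onset for b in self.bursts]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ParameterError("bursts must be strictly ordered by onset")
        for a, b in zip(self.bursts, self.bursts[1:]):
            if b.onset < a.offset:
                raise ParameterError("consecutive bursts must not overlap")

    def __len__(self) -> int:
        return len(self.bursts)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([b.onset for b in self.bursts])

    @property
    def offsets(self) -> np.ndarray:
        return np.array([b.offset for b in self.bursts])

    def restrict(self, start: float, end: float) -> "BurstTrain":
        """Bursts whose onset lies in [start, end]."""
        kept = [b for b in self.bursts if start <= b.onset <= end]
        return BurstTrain(self.channel, kept, self.detection_params, list(self.flags))


@dataclass
class Episode:
    """A span of analyzable activity on the reference channel."""

    start: float
    end: float
    kind: str  # "rhythmic" | "irregular"
    n_bursts_reference: int

    def __post_init__(self) -> None:
        if self.kind not in ("rhythmic", "irregular"):
            raise ParameterError(f"unknown episode kind {self.kind!r}")
        if self.kind == "rhythmic" and self.n_bursts_reference < 10:
            raise ParameterError("rhythmic episodes require >= 10 reference bursts")
        if self.kind == "irregular" and (self.end - self.start) < 10.0 - 1e-9:
            raise ParameterError("irregular episodes must span >= 10 s")

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_bursts(
    env: Envelope,
    k_on: float = 3.0,
    k_off: float = 1.5,
    min_burst: float = 0.05,
    min_gap: float = 0.05,
) -> BurstTrain:
    """Hysteresis burst detection on an envelope.

    Onset fires when a bin reaches ``baseline + k_on * MAD`` and the burst
    stays open until a bin falls below ``baseline + k_off * MAD``.  A flat
    envelope (zero spread) yields an empty train flagged ``flat-envelope``.
    Onset/offset times are bin-edge aligned; the peak is the maximum bin.
    """
    if not (k_on > k_off > 0):
        raise ParameterError(f"need k_on > k_off > 0, got k_on={k_on}, k_off={k_off}")
    if min_burst < env.bin_width or min_gap < env.bin_width:
        raise ParameterError("min_burst and min_gap must be >= the envelope bin width")

    params = {
        "k_on": k_on,
        "k_off": k_off,
        "min_burst_s": min_burst,
        "min_gap_s": min_gap,
        "bin_width_s": env.bin_width,
    }
    v = env.values
    if v.size == 0:
        return BurstTrain(env.source_channel, [], params, ["empty-envelope"])
    baseline = float(np.percentile(v, 20))
    spread = float(np.median(np.abs(v - np.median(v))))
    flags: list[str] = []
    if spread == 0.0:
        # Zero MAD can only occur on an (essentially) noise-free envelope
        # whose baseline bins are identical; place the onset threshold at 10%
        # of the dynamic range so weak amplitude-modulated bursts still mark.
        value_range = float(v.max() - baseline)
        if value_range <= 0.0:
            return BurstTrain(env.source_channel, [], params | {"baseline": baseline, "spread": 0.0}, ["flat-envelope"])
        spread = value_range / (10.0 * k_on)
        flags.append("zero-mad-range-fallback")
    params.update({"baseline": baseline, "spread": spread})

    th_on = baseline + k_on * spread
    th_off = baseline + k_off * spread
    params.update({"threshold_on": th_on, "threshold_off": th_off})

    # State machine over bins: segments as [first_bin, last_bin] inclusive.
    segments: list[tuple[int, int]] = []
    open_start = None
    for i, x in enumerate(v):
        if open_start is None:
            if x >= th_on:
                open_start = i
        else:
            if x < th_off:
                segments.append((open_start, i - 1))
                open_start = None
    if open_start is not None:
        segments.append((open_start, v.size - 1))

    # Discard sub-min_burst segments first so isolated noise bins cannot be
    # merged into genuine bursts, then merge across short gaps.
    w = env.bin_width
    segments = [(a, b) for a, b in segments if (b - a + 1) * w >= min_burst - 1e-12]
    merged: list[tuple[int, int]] = []
    for a, b in segments:
        if merged and (a - merged[-1][1] - 1) * w < min_gap - 1e-12:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    bursts = []
    for a, b in merged:
        seg = v[a : b + 1]
        k = int(np.argmax(seg))
        bursts.append(
            Burst(
                onset=env.t0 + a * w,
                offset=env.t0 + (b + 1) * w,
                peak_amplitude=float(seg[k]),
                peak_time=env.t0 + (a + k + 0.5) * w,
            )
        )
    return BurstTrain(env.source_channel, bursts, params, flags)


def _cycle_cv(onsets: np.ndarray) -> float:
    cycles = np.diff(onsets)
    if cycles.size < 2:
        return 0.0
    mean = cycles.mean()
    if mean <= 0:
        return np.inf
    return cycles.std(ddof=1) / mean


def find_episodes(
    ref: BurstTrain,
    max_cycle_cv: float = 0.5,
    duration_floor: float = 10.0,
    min_bursts: int = 10,
) -> list[Episode]:
    """Partition a reference burst train into rhythmic and irregular episodes.

    Greedy left-to-right scan: from each starting burst the run is extended
    while its cycle-duration CV stays at or below ``max_cycle_cv``; a run of
    at least ``min_bursts`` bursts becomes a rhythmic episode.  Bursts not
    absorbed into any rhythmic run are grouped into maximal leftover spans;
    a span of at least ``duration_floor`` seconds becomes an irregular
    episode.  Episodes never overlap and rhythmic takes precedence.
    """
    bursts = ref.bursts
    n = len(bursts)
    episodes: list[Episode] = []
    leftover: list[Burst] = []

    def flush_leftover() -> None:
        if leftover and (leftover[-1].offset - leftover[0].onset) >= duration_floor:
            episodes.append(
                Episode(
                    start=leftover[0].onset,
                    end=leftover[-1].offset,
                    kind="irregular",
                    n_bursts_reference=len(leftover),
                )
            )
        leftover.clear()

    i = 0
    onsets = ref.onsets
    while i < n:
        # Extend a candidate rhythmic run [i, j] while CV permits.
        j = i
        while j + 1 < n and _cycle_cv(onsets[i : j + 2]) <= max_cycle_cv:
            j += 1
        if j - i + 1 >= min_bursts:
            flush_leftover()
            episodes.append(
                Episode(
                    start=bursts[i].onset,
                    end=bursts[j].offset,
                    kind="rhythmic",
                    n_bursts_reference=j - i + 1,
                )
            )
            i = j + 1
        else:
            leftover.append(bursts[i])
            i += 1
    flush_leftover()
    return episodes
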