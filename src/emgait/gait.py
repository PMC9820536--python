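"""Per-animal locomotor parameters: cycle duration, burst duration, peak
amplitude, and their summaries (mean, SD, SEM, CV = SD/mean).

The step cycle is defined onset-to-onset of consecutive bursts of the same
muscle; burst duration is offset minus onset; peak amplitude is the maximum
of the (rectified-integrated) envelope within the burst.  Group statistics
operate on these per-animal summaries, never on pooled steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bursts import BurstTrain, Episode
from .errors import InsufficientDataError, UsageError
from .io import ChannelLabel
from .preprocess import Envelope

PARAMETERS = ("cycle_duration", "burst_duration", "peak_amplitude")


@dataclass
class CycleSeries:
    """Step-cycle durations (s) of one muscle within one episode."""

    animal_id: str
    muscle: ChannelLabel
    cycles: list[float]
    episode: "Episode | None" = None

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.cycles):
            raise UsageError("cycle durations must be positive")

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass
class ParamSummary:
    """Summary statistics of one locomotor parameter for one animal."""

    parameter: str
    mean: float
    sd: float
    sem: float
    cv: "float | None"
    n: int
    flags: list[str] = field(default_factory=list)


def cycle_durations(
    train: BurstTrain,
    episode: Episode,
    animal_id: str = "",
) -> CycleSeries:
    """Onset-to-onset intervals between consecutive bursts inside the episode.

    With fewer than two bursts in the episode the series is empty.
    """
    sub = train.restrict(episode.start, episode.end)
    onsets = sub.onsets
    cycles = np.diff(onsets).tolist() if onsets.size >= 2 else []
    return CycleSeries(animal_id=animal_id, muscle=train.channel, cycles=cycles, episode=episode)


def burst_durations(train: BurstTrain, episode: Episode) -> list[float]:
    """Offset minus onset for each burst inside the episode."""
    sub = train.restrict(episode.start, episode.end)
    return [b.duration for b in sub.bursts]


def peak_amplitudes(
    env: Envelope,
    train: BurstTrain,
    episode: Episode,
) -> list[float]:
    """Per-burst maximum of the envelope within [onset, offset].

    The envelope and the train must come from the same channel; the
    amplitude-analysis convention asks for at least 10 consecutive steps, so
    episodes with fewer than 10 bursts produce a warning, not an error.
    """
    if str(env.source_channel) != str(train.channel):
        raise UsageError(
            f"channel mismatch: envelope is {env.source_channel}, train is {train.channel}"
        )
    sub = train.restrict(episode.start, episode.end)
    if len(sub) < 10:
        warnings.warn(
            f"only {len(sub)} bursts in episode; amplitude analysis conventionally "
            "requires >= 10 consecutive steps",
            stacklevel=2,
        )
    peaks = []
    for b in sub.bursts:
        i0 = max(env.time_to_bin(b.onset), 0)
        i1 = min(env.time_to_bin(b.offset) + 1, env.n_bins)
        if i1 <= i0:
            i1 = min(i0 + 1, env.n_bins)
        peaks.append(float(env.values[i0:i1].max()))
    return peaks


def summarize(values: "list[float] | np.ndarray", parameter: str) -> ParamSummary:
    """Mean, sample SD (n-1), SEM and CV = SD/mean of one parameter.

    CV is reported as None (missing) when the mean is non-positive.
    """
    if parameter not in PARAMETERS:
        raise UsageError(f"unknown parameter {parameter!r}; expected one of {PARAMETERS}")
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(
            f"need at least 2 values to summarize {parameter}, got {x.size}"
        )
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    sem = sd / np.sqrt(x.size)
    flags = []
    if mean > 0:
        cv = sd / mean
    else:
        cv = None
        flags.append("cv-undefined")
    return ParamSummary(parameter=parameter, mean=mean, sd=sd, sem=float(sem), cv=cv, n=int(x.size), flags=flags)
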