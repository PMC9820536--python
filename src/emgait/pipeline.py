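"""End-to-end analysis: recording -> envelopes -> bursts -> episode ->
gait metrics + coordination, and cohort/drug-trial tables.

``analyze_recording`` runs one animal through the full chain and returns an
``AnimalAnalysis``; ``analyze_cohort`` tidies a list of analyses into
per-animal metric and coordination tables ready for the group-comparison
battery; ``drug_ratio_table`` forms the per-animal post/pre ratios tested
against unity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bursts import BurstTrain, Episode, detect_bursts, find_episodes
from .circstats import CircStatResult, mean_vector, onset_phases
from .errors import InsufficientDataError, UsageError
from .gait import ParamSummary, burst_durations, cycle_durations, peak_amplitudes, summarize
from .io import EmgRecording
from .preprocess import AMPLITUDE_BIN_S, BURST_BIN_S, Envelope, bandpass, integrate


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the standard analysis chain."""

    bandpass_enabled: bool = True
    filter_low_hz: float = 100.0
    filter_high_hz: float = 999.0
    filter_order: int = 4
    burst_bin_s: float = BURST_BIN_S          # envelope for burst marking
    amplitude_bin_s: float = AMPLITUDE_BIN_S  # envelope for amplitude analysis
    k_on: float = 3.0
    k_off: float = 1.5
    min_burst_s: float = 0.05
    min_gap_s: float = 0.05
    episode_max_cycle_cv: float = 0.5
    episode_duration_floor_s: float = 10.0
    reference_channel: str = "Sol-L"
    alpha: float = 0.05


@dataclass
class AnimalAnalysis:
    """All per-animal outputs of the pipeline for one recording."""

    animal_id: str
    group: str
    condition: str
    episode: Episode
    summaries: dict[tuple[str, str], ParamSummary]  # (channel, parameter) -> summary
    coordination: list[CircStatResult]
    trains: dict[str, BurstTrain] = field(default_factory=dict)

    def coordination_for(self, pairing: str, side: str = "L") -> "CircStatResult | None":
        for res in self.coordination:
            if res.pairing == pairing and (pairing == "interlimb" or res.test.endswith(side)):
                return res
        return None


def _burst_trains(
    rec: EmgRecording, cfg: PipelineConfig
) -> tuple[dict[str, BurstTrain], dict[str, tuple[Envelope, Envelope]]]:
    """Per-channel burst trains plus (burst, amplitude) envelope pair."""
    work = rec
    if cfg.bandpass_enabled:
        work = bandpass(rec, cfg.filter_low_hz, cfg.filter_high_hz, cfg.filter_order)
    trains: dict[str, BurstTrain] = {}
    envelopes: dict[str, tuple[Envelope, Envelope]] = {}
    for name in rec.channel_names:
        burst_env = integrate(work, name, window=cfg.burst_bin_s)
        amp_env = integrate(work, name, window=cfg.amplitude_bin_s)
        trains[name] = detect_bursts(
            burst_env, k_on=cfg.k_on, k_off=cfg.k_off,
            min_burst=cfg.min_burst_s, min_gap=cfg.min_gap_s,
        )
        envelopes[name] = (burst_env, amp_env)
    return trains, envelopes


def analyze_recording(
    rec: EmgRecording,
    config: "PipelineConfig | None" = None,
) -> AnimalAnalysis:
    """Run the full chain on one recording.

    The analysis episode is the first rhythmic episode of the reference
    channel (falling back to the first irregular one).  Gait summaries are
    computed per channel; coordination for Sol-L/Sol-R (interlimb) and
    Sol/TA per side (intralimb).
    """
    cfg = config if config is not None else PipelineConfig()
    trains, envelopes = _burst_trains(rec, cfg)
    if cfg.reference_channel not in trains:
        raise UsageError(f"reference channel {cfg.reference_channel} not in recording")
    episodes = find_episodes(
        trains[cfg.reference_channel],
        max_cycle_cv=cfg.episode_max_cycle_cv,
        duration_floor=cfg.episode_duration_floor_s,
    )
    rhythmic = [e for e in episodes if e.kind == "rhythmic"]
    if rhythmic:
        episode = rhythmic[0]
    elif episodes:
        episode = episodes[0]
    else:
        raise InsufficientDataError(
            f"no analyzable episode in recording {rec.animal_id} "
            "(need >= 10 rhythmic bursts or >= 10 s of irregular activity)"
        )

    summaries: dict[tuple[str, str], ParamSummary] = {}
    for name, train in trains.items():
        _, amp_env = envelopes[name]
        series = cycle_durations(train, episode, animal_id=rec.animal_id)
        if len(series) >= 2:
            summaries[(name, "cycle_duration")] = summarize(series.cycles, "cycle_duration")
        durations = burst_durations(train, episode)
        if len(durations) >= 2:
            summaries[(name, "burst_duration")] = summarize(durations, "burst_duration")
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            peaks = peak_amplitudes(amp_env, train, episode)
        if len(peaks) >= 2:
            summaries[(name, "peak_amplitude")] = summarize(peaks, "peak_amplitude")

    coordination = []
    names = rec.channel_names
    pairs = []
    if "Sol-L" in names and "Sol-R" in names:
        pairs.append(("Sol-L", "Sol-R", "interlimb"))
    for s in ("L", "R"):
        if f"Sol-{s}" in names and f"TA-{s}" in names:
            pairs.append((f"Sol-{s}", f"TA-{s}", "intralimb"))
    for ref_name, test_name, pairing in pairs:
        try:
            ps = onset_phases(trains[ref_name], trains[test_name], episode,
                              pairing=pairing, animal_id=rec.animal_id)
        except InsufficientDataError:
            continue
        if len(ps) == 0:
            continue
        coordination.append(mean_vector(ps, alpha=cfg.alpha))

    return AnimalAnalysis(
        animal_id=rec.animal_id,
        group=rec.group,
        condition=rec.condition,
        episode=episode,
        summaries=summaries,
        coordination=coordination,
        trains=trains,
    )


def analyze_cohort(
    recordings: "list[EmgRecording]",
    config: "PipelineConfig | None" = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze every recording; return tidy (metrics, coordination) tables.

    metrics columns: animal_id, group, condition, muscle, parameter, mean,
    sd, sem, cv, n.  coordination columns: animal_id, group, condition,
    pairing, reference, test, n, mean_angle_deg, r, cR, rayleigh_p,
    coordinated.  Recordings without an analyzable episode are skipped.
    """
    metric_rows = []
    coord_rows = []
    for rec in recordings:
        try:
            analysis = analyze_recording(rec, config)
        except InsufficientDataError:
            continue
        for (muscle, parameter), s in analysis.summaries.items():
            metric_rows.append(
                dict(animal_id=analysis.animal_id, group=analysis.group,
                     condition=analysis.condition, muscle=muscle, parameter=parameter,
                     mean=s.mean, sd=s.sd, sem=s.sem, cv=s.cv, n=s.n)
            )
        for res in analysis.coordination:
            coord_rows.append(
                dict(animal_id=analysis.animal_id, group=analysis.group,
                     condition=analysis.condition, pairing=res.pairing,
                     reference=res.reference, test=res.test, n=res.n,
                     mean_angle_deg=res.mean_angle, r=res.r, cR=res.cR,
                     rayleigh_p=res.rayleigh_p, coordinated=res.coordinated)
            )
    return pd.DataFrame(metric_rows), pd.DataFrame(coord_rows)


def drug_ratio_table(
    pre: "list[AnimalAnalysis]",
    post: "list[AnimalAnalysis]",
) -> pd.DataFrame:
    """Per-animal post/pre ratios of the drug-trial endpoints.

    One row per (animal, quantity); quantities are the mean cycle duration,
    Sol/TA burst duration and peak amplitude (left side), and the interlimb
    and intralimb coordination strength r.  Animals are matched by id.
    """
    post_by_id = {a.animal_id: a for a in post}
    rows = []
    for a_pre in pre:
        a_post = post_by_id.get(a_pre.animal_id)
        if a_post is None:
            continue
        for muscle, parameter, label in [
            ("Sol-L", "cycle_duration", "cycle_duration"),
            ("Sol-L", "burst_duration", "sol_burst_duration"),
            ("Sol-L", "peak_amplitude", "sol_peak_amplitude"),
            ("TA-L", "burst_duration", "ta_burst_duration"),
            ("TA-L", "peak_amplitude", "ta_peak_amplitude"),
        ]:
            s_pre = a_pre.summaries.get((muscle, parameter))
            s_post = a_post.summaries.get((muscle, parameter))
            if s_pre is None or s_post is None or s_pre.mean <= 0:
                continue
            rows.append(dict(animal_id=a_pre.animal_id, quantity=label,
                             pre=s_pre.mean, post=s_post.mean,
                             ratio=s_post.mean / s_pre.mean))
        for pairing, label in [("interlimb", "interlimb_r"), ("intralimb", "intralimb_r")]:
            c_pre = a_pre.coordination_for(pairing)
            c_post = a_post.coordination_for(pairing)
            if c_pre is None or c_post is None or c_pre.r <= 0:
                continue
            rows.append(dict(animal_id=a_pre.animal_id, quantity=label,
                             pre=c_pre.r, post=c_post.r, ratio=c_post.r / c_pre.r))
    return pd.DataFrame(rows)
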