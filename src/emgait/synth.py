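"""Synthetic locomotor EMG generator.

Emulates treadmill hindlimb EMG of four muscles (Sol-L/R, TA-L/R) with the
statistical structure the analysis assumes: a reference Sol-L burst train
with Gaussian cycle jitter; Sol-R onsets coupled at a configurable interlimb
phase (default 180 deg, alternating gait) with von Mises phase noise; TA
onsets coupled to the ipsilateral Sol at the intralimb phase (default 180
deg, flexor-extensor alternation); long stance-related Sol bursts (duty
0.35) and brief swing-related TA bursts (duty 0.15).  Within bursts the
signal is amplitude-scaled band-limited Gaussian noise (or a constant-
magnitude square carrier when ``carrier_band`` is None, for exact
constructions); outside bursts, Gaussian baseline noise.

A drug-perturbation transform regenerates an animal with scaled burst
amplitudes/durations and reduced phase concentration, mimicking the
direction of a 5-HT2-antagonist (cyproheptadine-like) collapse of the
locomotor pattern.  These are generative conveniences with known ground
truth, not claims about real recordings.

Everything is deterministic for a fixed (seed, animal_index).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .io import ChannelLabel, EmgRecording

_SQUARE_CARRIER_HZ = 250.0


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generative parameters for one cohort of synthetic animals."""

    n_animals: int = 5
    group_label: str = "TTx2EB"
    duration: float = 20.0
    sampling_rate: float = 2000.0
    cycle_mean: float = 1.0
    cycle_jitter_sd: float = 0.05
    sol_duty: float = 0.35
    ta_duty: float = 0.15
    interlimb_phase: float = 180.0
    intralimb_phase: float = 180.0
    phase_kappa: float = 8.0
    sol_amp: float = 1.0
    ta_amp: float = 0.8
    amp_jitter_cv: float = 0.15
    carrier_band: "tuple[float, float] | None" = (150.0, 400.0)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ConfigError("n_animals must be >= 1")
        if not (0 < self.sol_duty < 1 and 0 < self.ta_duty < 1):
            raise ConfigError("duty cycles must lie strictly in (0, 1)")
        if self.phase_kappa < 0:
            raise ConfigError("phase_kappa must be >= 0")
        if self.sol_amp <= 0 or self.ta_amp <= 0:
            raise ConfigError("burst amplitudes must be > 0")
        if self.cycle_mean <= 0 or self.duration <= 0 or self.sampling_rate <= 0:
            raise ConfigError("cycle_mean, duration and sampling_rate must be > 0")
        if self.carrier_band is not None:
            low, high = self.carrier_band
            if not (0 < low < high < self.sampling_rate / 2):
                raise ConfigError("carrier_band must satisfy 0 < low < high < Nyquist")


@dataclass(frozen=True)
class DrugEffectConfig:
    """Multiplicative perturbation emulating a serotonergic blockade."""

    amp_scale_sol: float = 0.45
    amp_scale_ta: float = 0.5
    sol_duration_scale: float = 0.65
    ta_duration_scale: float = 2.2
    phase_kappa_post: float = 0.7
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.amp_scale_sol, self.amp_scale_ta,
               self.sol_duration_scale, self.ta_duration_scale) <= 0:
            raise ConfigError("drug scales must be > 0")
        if self.phase_kappa_post < 0:
            raise ConfigError("phase_kappa_post must be >= 0")


def treated_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """Preset emulating the treated (remyelinated) cohort: strong phase
    coupling, low cycle jitter, brief TA bursts, higher Sol amplitude."""
    base = dict(
        n_animals=5, group_label="TTx2EB", cycle_jitter_sd=0.05, phase_kappa=8.0,
        sol_duty=0.35, ta_duty=0.15, sol_amp=1.0, ta_amp=0.8, amp_jitter_cv=0.15,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticCohortConfig(**base)


def control_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """Preset emulating the untreated control cohort: weak, near-uniform
    phase coupling, high cycle jitter, long irregular TA bursts, lower Sol
    amplitude and higher step-to-step amplitude variability."""
    base = dict(
        n_animals=7, group_label="TTnoEB", cycle_jitter_sd=0.20, phase_kappa=0.5,
        sol_duty=0.35, ta_duty=0.30, sol_amp=0.55, ta_amp=0.8, amp_jitter_cv=0.30,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticCohortConfig(**base)


def _von_mises_deg(rng: np.random.Generator, mu_deg: float, kappa: float, size: int) -> np.ndarray:
    """von Mises phase samples in degrees; kappa = inf (or huge) disables jitter,
    kappa = 0 is uniform on the circle."""
    if not math.isfinite(kappa) or kappa > 1e8:
        return np.full(size, mu_deg % 360.0)
    if kappa == 0:
        return rng.uniform(0.0, 360.0, size)
    draws = rng.vonmises(np.deg2rad(mu_deg), kappa, size)
    return np.rad2deg(draws) % 360.0


def _events_to_signal(
    events: "list[tuple[float, float, float]]",
    n: int,
    fs: float,
    carrier: "np.ndarray | None",
    noise: np.ndarray,
) -> np.ndarray:
    """Render (onset, duration, amplitude) events into a raw signed signal."""
    x = noise.copy()
    if carrier is None:
        half = max(int(round(fs / (2 * _SQUARE_CARRIER_HZ))), 1)
        idx = np.arange(n)
        square = np.where((idx // half) % 2 == 0, 1.0, -1.0)
    for onset, dur, amp in events:
        i0 = max(int(round(onset * fs)), 0)
        i1 = min(int(round((onset + dur) * fs)), n)
        if i1 <= i0:
            continue
        if carrier is None:
            x[i0:i1] += amp * square[i0:i1]
        else:
            x[i0:i1] += amp * carrier[i0:i1]
    return x


def generate_animal(
    cfg: SyntheticCohortConfig,
    animal_index: int,
    condition: str = "none",
    stream: int = 0,
) -> EmgRecording:
    """Generate one synthetic animal's four-channel recording.

    Deterministic for fixed (cfg.seed, stream, animal_index); distinct
    animal indices (or streams) draw from independent substreams.
    """
    ss = np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, stream, animal_index])
    r_timing, r_phase, r_amp, r_noise, r_carrier = [
        np.random.default_rng(child) for child in ss.spawn(5)
    ]
    fs = cfg.sampling_rate
    n = int(round(cfg.duration * fs))

    # Reference Sol-L onsets with Gaussian cycle jitter (floored at 20% of the
    # mean so cycles stay positive).
    onsets = []
    t = 0.25 * cfg.cycle_mean
    while t < cfg.duration - 0.05 * cfg.cycle_mean:
        onsets.append(t)
        cycle = r_timing.normal(cfg.cycle_mean, cfg.cycle_jitter_sd)
        t += max(cycle, 0.2 * cfg.cycle_mean)
    onsets = np.asarray(onsets)
    cycles = np.diff(onsets)
    n_cycles = cycles.size

    inter = _von_mises_deg(r_phase, cfg.interlimb_phase, cfg.phase_kappa, n_cycles)
    intra_l = _von_mises_deg(r_phase, cfg.intralimb_phase, cfg.phase_kappa, n_cycles)
    intra_r = _von_mises_deg(r_phase, cfg.intralimb_phase, cfg.phase_kappa, n_cycles)

    sol_l = [(onsets[k], cfg.sol_duty * cycles[k]) for k in range(n_cycles)]
    sol_r = [(onsets[k] + inter[k] / 360.0 * cycles[k], cfg.sol_duty * cycles[k])
             for k in range(n_cycles)]
    ta_l = [(onsets[k] + intra_l[k] / 360.0 * cycles[k], cfg.ta_duty * cycles[k])
            for k in range(n_cycles)]
    ta_r = [(sol_r[k][0] + intra_r[k] / 360.0 * cycles[k], cfg.ta_duty * cycles[k])
            for k in range(n_cycles)]

    def with_amps(windows: "list[tuple[float, float]]", amp: float) -> list:
        events: list[tuple[float, float, float]] = []
        for onset, dur in sorted(windows):
            if events and onset < events[-1][0] + events[-1][1]:
                # phase jitter collided with the previous burst: truncate the
                # previous burst at this onset (dropping onsets would censor
                # the sampled phase distribution non-uniformly)
                prev_on, _, prev_amp = events[-1]
                if onset - prev_on <= 0:
                    continue  # same onset time; keep the earlier burst
                events[-1] = (prev_on, float(onset - prev_on), prev_amp)
            if cfg.amp_jitter_cv > 0:
                a = amp * max(1.0 + cfg.amp_jitter_cv * float(r_amp.standard_normal()), 0.05)
            else:
                a = amp
            events.append((float(onset), float(dur), float(a)))
        return events

    channel_events = {
        "Sol-L": with_amps(sol_l, cfg.sol_amp),
        "Sol-R": with_amps(sol_r, cfg.sol_amp),
        "TA-L": with_amps(ta_l, cfg.ta_amp),
        "TA-R": with_amps(ta_r, cfg.ta_amp),
    }

    if cfg.carrier_band is not None:
        sos = sps.butter(4, cfg.carrier_band, btype="bandpass", fs=fs, output="sos")

    columns = []
    for name in ("Sol-L", "Sol-R", "TA-L", "TA-R"):
        noise = cfg.noise_sd * r_noise.standard_normal(n) if cfg.noise_sd > 0 else np.zeros(n)
        if cfg.carrier_band is not None:
            carrier = sps.sosfiltfilt(sos, r_carrier.standard_normal(n))
            carrier /= np.mean(np.abs(carrier))  # rectified mean == 1
        else:
            carrier = None
        columns.append(_events_to_signal(channel_events[name], n, fs, carrier, noise))

    return EmgRecording(
        animal_id=f"{cfg.group_label}-{animal_index:02d}",
        group=cfg.group_label,
        condition=condition,
        sampling_rate=fs,
        channels=[ChannelLabel.parse(c) for c in ("Sol-L", "Sol-R", "TA-L", "TA-R")],
        signal=np.column_stack(columns),
        meta={"generator": {"seed": cfg.seed, "stream": stream, "animal_index": animal_index,
                            "config": dataclasses.asdict(cfg),
                            "events": {k: [list(e) for e in v]
                                       for k, v in channel_events.items()}}},
    )


def generate_cohort(
    cfg_treated: "SyntheticCohortConfig | None" = None,
    cfg_control: "SyntheticCohortConfig | None" = None,
) -> list[EmgRecording]:
    """Generate a treated-vs-control study: by default 5 strongly coordinated
    TTx2EB animals and 7 weakly coordinated TTnoEB animals."""
    cfg_treated = cfg_treated if cfg_treated is not None else treated_config()
    cfg_control = cfg_control if cfg_control is not None else control_config()
    recs = [generate_animal(cfg_treated, i) for i in range(cfg_treated.n_animals)]
    recs += [generate_animal(cfg_control, i, stream=1) for i in range(cfg_control.n_animals)]
    return recs


def apply_drug_effect(
    cfg: SyntheticCohortConfig,
    drug: "DrugEffectConfig | None" = None,
    animal_index: int = 0,
) -> tuple[EmgRecording, EmgRecording]:
    """Generate a (pre-drug, post-drug) pair for one animal.

    The post recording is an independent realization of the same animal with
    burst amplitudes and durations rescaled and phase concentration replaced
    by ``phase_kappa_post``.  Raises ConfigError if a scaled duty cycle
    reaches 1 (bursts would outlast their cycle).
    """
    drug = drug if drug is not None else DrugEffectConfig()
    post_cfg = dataclasses.replace(
        cfg,
        sol_amp=cfg.sol_amp * drug.amp_scale_sol,
        ta_amp=cfg.ta_amp * drug.amp_scale_ta,
        sol_duty=cfg.sol_duty * drug.sol_duration_scale,
        ta_duty=cfg.ta_duty * drug.ta_duration_scale,
        phase_kappa=drug.phase_kappa_post,
    )  # duty >= 1 rejected by SyntheticCohortConfig validation
    pre = generate_animal(cfg, animal_index, condition="pre_drug", stream=0)
    post = generate_animal(post_cfg, animal_index, condition="post_drug",
                           stream=1000 + (drug.seed & 0xFFFF))
    return pre, post
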