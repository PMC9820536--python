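"""Circular statistics for burst-onset phase coordination.

Phases are the positions of a test muscle's burst onsets within the
reference muscle's step cycles, expressed in degrees on [0, 360): 0/360
means synchrony of the two muscles' onsets, 180 means strict alternation
(the normal pattern both for left/right soleus — interlimb — and for
soleus/tibialis anterior within a limb — intralimb).

The strength of coordination is the length r of the mean resultant vector
(0 = no coupling, 1 = perfect phase locking).  Coupling is declared when r
exceeds the critical Rayleigh value cR at the chosen significance level.
Two-sample comparisons of phase distributions use Watson's U² test;
paired pre/post comparisons use Moore's rank-weighted modified Rayleigh
test on the paired difference vectors.

Angles are handled internally in radians and reported in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bursts import BurstTrain, Episode
from .errors import DataError, InsufficientDataError, UsageError
from .io import ChannelLabel, EmgRecording

DEFAULT_ALPHA = 0.05
DEFAULT_PERMUTATIONS = 9999


@dataclass
class PhaseSampleSet:
    """Burst-onset phases (degrees in [0, 360)) of a test muscle within
    reference-muscle cycles."""

    reference: ChannelLabel
    test: ChannelLabel
    phases: np.ndarray
    pairing: str = "interlimb"  # "interlimb" | "intralimb"
    animal_id: str = ""
    multiplicity_flag: bool = False  # some cycles held > 1 test onset

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.size and not np.all(np.isfinite(self.phases)):
            raise DataError("phases must be finite")
        self.phases = np.mod(self.phases, 360.0)
        if self.pairing not in ("interlimb", "intralimb"):
            raise UsageError(f"unknown pairing {self.pairing!r}")

    def __len__(self) -> int:
        return self.phases.size


@dataclass
class CircStatResult:
    """Mean-vector summary of one phase sample with the Rayleigh criterion."""

    mean_angle: float  # degrees in [0, 360)
    r: float
    n: int
    rayleigh_p: float
    cR: float
    coordinated: bool
    alpha: float = DEFAULT_ALPHA
    pairing: str = ""
    reference: str = ""
    test: str = ""
    animal_id: str = ""


@dataclass
class AngularTestResult:
    """Outcome of a two-sample or paired angular hypothesis test."""

    test_name: str  # "watson_u2" | "moore_paired"
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str  # "asymptotic" | "permutation"
    seed: "int | None" = None
    n_permutations: "int | None" = None


def _phases_array(phases: "PhaseSampleSet | Sequence[float] | np.ndarray") -> np.ndarray:
    if isinstance(phases, PhaseSampleSet):
        return phases.phases
    return np.mod(np.asarray(phases, dtype=float), 360.0)


def onset_phases(
    ref: BurstTrain,
    test: BurstTrain,
    episode: Episode,
    pairing: str = "interlimb",
    animal_id: str = "",
) -> PhaseSampleSet:
    """Phase of each test-muscle burst onset within the reference cycles.

    For each reference cycle [onset_i, onset_{i+1}) inside the episode the
    phase is 360 * (t_test - onset_i) / cycle_i for the test onset falling in
    the cycle.  Cycles with no test onset are skipped; cycles with several
    use the first and set ``multiplicity_flag``.
    """
    ref_sub = ref.restrict(episode.start, episode.end)
    if len(ref_sub) < 2:
        raise InsufficientDataError("need >= 2 reference bursts in the episode")
    test_onsets = test.restrict(episode.start, episode.end).onsets
    ref_onsets = ref_sub.onsets
    phases = []
    multiplicity = False
    for a, b in zip(ref_onsets[:-1], ref_onsets[1:]):
        inside = test_onsets[(test_onsets >= a) & (test_onsets < b)]
        if inside.size == 0:
            continue
        if inside.size > 1:
            multiplicity = True
        phases.append(360.0 * (inside[0] - a) / (b - a))
    return PhaseSampleSet(
        reference=ref.channel,
        test=test.channel,
        phases=np.array(phases),
        pairing=pairing,
        animal_id=animal_id,
        multiplicity_flag=multiplicity,
    )


def rayleigh_p(n: int, r: float) -> float:
    """Rayleigh uniformity test p-value (finite-n approximation).

    With R = n*r, p = exp(sqrt(1 + 4n + 4(n² - R²)) - (1 + 2n)); accurate to
    three decimals for n >= 10 and adequate down to very small n.
    """
    if n < 1:
        raise InsufficientDataError("Rayleigh test requires n >= 1")
    R = n * r
    arg = 1.0 + 4.0 * n + 4.0 * (n * n - R * R)
    p = math.exp(math.sqrt(max(arg, 0.0)) - (1.0 + 2.0 * n))
    return min(p, 1.0)


def critical_r(n: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Critical Rayleigh r-value cR: the r at which ``rayleigh_p`` equals alpha.

    Solved in closed form from the same finite-n expression; r > cR declares
    significant phase concentration (coordination) at level alpha.
    """
    if n < 1:
        raise InsufficientDataError("critical_r requires n >= 1")
    if not (0 < alpha < 1):
        raise UsageError("alpha must be in (0, 1)")
    k = (1.0 + 2.0 * n) + math.log(alpha)
    if k <= 0:  # alpha so small the criterion cannot be met at this n
        return 1.0
    R2 = (1.0 + 4.0 * n + 4.0 * n * n - k * k) / 4.0
    if R2 <= 0:
        return 0.0
    return min(math.sqrt(R2) / n, 1.0)


def mean_vector(
    phases: "PhaseSampleSet | Sequence[float] | np.ndarray",
    alpha: float = DEFAULT_ALPHA,
) -> CircStatResult:
    """Mean resultant vector, Rayleigh p, and the cR coordination criterion."""
    x = _phases_array(phases)
    n = x.size
    if n == 0:
        raise InsufficientDataError("mean_vector requires at least one phase")
    rad = np.deg2rad(x)
    C = np.cos(rad).mean()
    S = np.sin(rad).mean()
    r = float(np.hypot(C, S))
    r = min(r, 1.0)
    mean_angle = float(np.rad2deg(np.arctan2(S, C)) % 360.0)
    p = rayleigh_p(n, r)
    cR = critical_r(n, alpha)
    result = CircStatResult(
        mean_angle=mean_angle,
        r=r,
        n=int(n),
        rayleigh_p=p,
        cR=cR,
        coordinated=bool(r > cR),
        alpha=alpha,
    )
    if isinstance(phases, PhaseSampleSet):
        result.pairing = phases.pairing
        result.reference = str(phases.reference)
        result.test = str(phases.test)
        result.animal_id = phases.animal_id
    return result


# ---------------------------------------------------------------------------
# Watson's two-sample U² test
# ---------------------------------------------------------------------------

def _watson_u2_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Watson's two-sample U² from pooled cumulative-fraction differences.

    Ties across samples are handled by averaging the cumulative difference
    within each tied group (weights = group multiplicities).
    """
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    labels = np.concatenate([np.ones(n1), np.zeros(n2)])
    order = np.argsort(pooled, kind="stable")
    x = pooled[order]
    z = labels[order]
    d = np.cumsum(z) / n1 - np.cumsum(1.0 - z) / n2
    # group tied pooled values: keep the final d of each group, weighted
    boundaries = np.nonzero(np.diff(x) != 0)[0]
    idx = np.concatenate([boundaries, [x.size - 1]])
    counts = np.diff(np.concatenate([[-1], idx]))
    dg = d[idx]
    N = n1 + n2
    dbar = float(np.sum(counts * dg)) / N
    return float(n1 * n2 / N**2 * np.sum(counts * (dg - dbar) ** 2))


def _watson_u2_asymptotic_p(u2: float, terms: int = 200) -> float:
    """P(U² >= u2) from the limiting distribution 2*sum (-1)^{m-1} exp(-2 m² π² u)."""
    if u2 <= 0:
        return 1.0
    m = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (m - 1) * np.exp(-2.0 * m**2 * np.pi**2 * u2))
    return float(min(max(p, 0.0), 1.0))


def watson_u2(
    a: "PhaseSampleSet | Sequence[float] | np.ndarray",
    b: "PhaseSampleSet | Sequence[float] | np.ndarray",
    method: str = "asymptotic",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: "int | None" = 0,
) -> AngularTestResult:
    """Watson's two-sample U² test for a difference between circular samples.

    ``method="asymptotic"`` uses the limiting series of the U² distribution;
    ``method="permutation"`` pools the two samples and recomputes U² under
    random relabelings (p = (1 + #{U²* >= U²}) / (1 + B), seeded).
    """
    xa = np.deg2rad(_phases_array(a))
    xb = np.deg2rad(_phases_array(b))
    # U² depends on the circular ordering only; reduce angles mod 2π.
    xa = np.mod(xa, 2 * np.pi)
    xb = np.mod(xb, 2 * np.pi)
    if xa.size < 4 or xb.size < 4:
        raise InsufficientDataError("watson_u2 requires n >= 4 per sample")
    u2 = _watson_u2_stat(xa, xb)
    if method == "asymptotic":
        p = _watson_u2_asymptotic_p(u2)
        return AngularTestResult("watson_u2", u2, p, int(xa.size), int(xb.size), "asymptotic")
    if method != "permutation":
        raise UsageError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    n1, n2 = xa.size, xb.size
    pooled = np.concatenate([xa, xb])
    count = 0
    # Vectorised permutation: U² depends only on which sorted pooled positions
    # belong to sample a; ties (rare for continuous phases) fall back to the
    # scalar tie-aware statistic.
    has_ties = np.unique(pooled).size != pooled.size
    if has_ties:
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if _watson_u2_stat(perm[:n1], perm[n1:]) >= u2 - 1e-15:
                count += 1
    else:
        order = np.argsort(pooled)
        N = n1 + n2

        def batch_u2(zs: np.ndarray) -> np.ndarray:
            d = np.cumsum(zs, axis=1) / n1 - np.cumsum(1.0 - zs, axis=1) / n2
            dbar = d.mean(axis=1, keepdims=True)
            return n1 * n2 / N**2 * np.sum((d - dbar) ** 2, axis=1)

        # Reference value through the identical code path so permuted
        # statistics exactly equal to the observed one count as >=.
        z_obs = np.concatenate([np.ones(n1), np.zeros(n2)])[None, order]
        u2_ref = float(batch_u2(z_obs)[0])
        batch = max(1, min(n_permutations, 4_000_000 // max(N, 1)))
        done = 0
        while done < n_permutations:
            m = min(batch, n_permutations - done)
            # random labelings: for each row, choose n1 positions for sample a
            u = rng.random((m, N))
            ranks = np.argsort(u, axis=1)
            z = np.zeros((m, N))
            np.put_along_axis(z, ranks[:, :n1], 1.0, axis=1)
            u2s = batch_u2(z[:, order])
            count += int(np.sum(u2s >= u2_ref - 1e-12))
            done += m
    p = (1 + count) / (1 + n_permutations)
    return AngularTestResult(
        "watson_u2", u2, float(p), int(n1), int(n2), "permutation",
        seed=seed, n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Moore's paired (modified Rayleigh) test
# ---------------------------------------------------------------------------

# Critical values of Moore's R* under the exact null (uniform difference-vector
# angles, fixed magnitude ranks 1..n), derived by 10^6-replicate Monte Carlo.
_MOORE_ALPHAS = (0.10, 0.05, 0.025, 0.01, 0.005, 0.001)
_MOORE_CRITICAL = {
    5: (0.9894, 1.0834, 1.1504, 1.2147, 1.2506, 1.3000),
    6: (0.9737, 1.0749, 1.1530, 1.2306, 1.2740, 1.3450),
    7: (0.9601, 1.0670, 1.1513, 1.2393, 1.2907, 1.3756),
    8: (0.9489, 1.0585, 1.1476, 1.2418, 1.2991, 1.3981),
    9: (0.9417, 1.0534, 1.1446, 1.2431, 1.3043, 1.4144),
    10: (0.9349, 1.0483, 1.1425, 1.2462, 1.3110, 1.4330),
    11: (0.9293, 1.0444, 1.1405, 1.2472, 1.3154, 1.4414),
    12: (0.9254, 1.0409, 1.1387, 1.2466, 1.3174, 1.4506),
    13: (0.9222, 1.0378, 1.1369, 1.2471, 1.3195, 1.4555),
    14: (0.9186, 1.0350, 1.1344, 1.2458, 1.3205, 1.4657),
    15: (0.9149, 1.0322, 1.1334, 1.2474, 1.3226, 1.4697),
    16: (0.9128, 1.0311, 1.1327, 1.2481, 1.3236, 1.4735),
    17: (0.9115, 1.0296, 1.1302, 1.2468, 1.3239, 1.4750),
    18: (0.9088, 1.0271, 1.1287, 1.2470, 1.3247, 1.4804),
    19: (0.9064, 1.0262, 1.1291, 1.2478, 1.3257, 1.4843),
    20: (0.9052, 1.0246, 1.1283, 1.2487, 1.3290, 1.4853),
    25: (0.9002, 1.0201, 1.1254, 1.2473, 1.3294, 1.4942),
    30: (0.8960, 1.0170, 1.1226, 1.2452, 1.3319, 1.4999),
    40: (0.8914, 1.0131, 1.1200, 1.2464, 1.3293, 1.4995),
    50: (0.8873, 1.0098, 1.1169, 1.2421, 1.3282, 1.5052),
    100: (0.8814, 1.0037, 1.1125, 1.2416, 1.3285, 1.5144),
}


def moore_critical_value(n: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Tabulated critical value of Moore's R* (nearest-n lookup)."""
    if alpha not in _MOORE_ALPHAS:
        raise UsageError(f"alpha must be one of {_MOORE_ALPHAS} for the table")
    j = _MOORE_ALPHAS.index(alpha)
    ns = sorted(_MOORE_CRITICAL)
    key = min(ns, key=lambda k: (abs(k - n), k))
    return _MOORE_CRITICAL[key][j]


def _moore_rstar(pre: np.ndarray, post: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Moore's R* and the (angle, rank) decomposition of the difference vectors."""
    dx = np.cos(post) - np.cos(pre)
    dy = np.sin(post) - np.sin(pre)
    mag = np.hypot(dx, dy)
    # average ranks for tied magnitudes (zero-difference pairs rank lowest)
    order = np.argsort(mag, kind="stable")
    ranks = np.empty(mag.size)
    ranks[order] = np.arange(1, mag.size + 1)
    for value in np.unique(mag):
        tied = mag == value
        if tied.sum() > 1:
            ranks[tied] = ranks[tied].mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(mag > 0, dx / np.where(mag > 0, mag, 1.0), 0.0)
        uy = np.where(mag > 0, dy / np.where(mag > 0, mag, 1.0), 0.0)
    n = mag.size
    X = float(np.sum(ranks * ux))
    Y = float(np.sum(ranks * uy))
    rstar = math.hypot(X, Y) / n**1.5
    return rstar, ranks, mag


def moore_paired(
    pairs: "Sequence[tuple[float, float]] | np.ndarray",
    method: str = "permutation",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: "int | None" = 0,
) -> AngularTestResult:
    """Moore's paired test for a consistent angular change between conditions.

    ``pairs`` are (pre_angle, post_angle) in degrees.  The paired difference
    vectors (cos post - cos pre, sin post - sin pre) are ranked by magnitude;
    the rank-weighted resultant R* = |sum rank_i * u_i| / n^(3/2) is compared
    with its null distribution (uniform difference-vector directions).
    ``method="permutation"`` samples that null directly with a seeded RNG;
    ``method="asymptotic"`` uses the large-n chi-square approximation
    p = exp(-6 n² R*² / ((n+1)(2n+1))).  Zero-difference pairs contribute a
    zero vector (lowest magnitude rank), so identical pre/post angles give
    R* = 0 and p ≈ 1.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise UsageError("pairs must be a sequence of (pre_angle, post_angle)")
    if not np.all(np.isfinite(arr)):
        raise DataError("angles must be finite")
    n = arr.shape[0]
    if n < 5:
        raise InsufficientDataError(f"moore_paired requires n >= 5 pairs, got {n}")
    pre = np.deg2rad(arr[:, 0])
    post = np.deg2rad(arr[:, 1])
    rstar, ranks, mag = _moore_rstar(pre, post)

    if method == "asymptotic":
        p = math.exp(-6.0 * n * n * rstar * rstar / ((n + 1.0) * (2.0 * n + 1.0)))
        return AngularTestResult("moore_paired", rstar, min(p, 1.0), int(n), int(n), "asymptotic")
    if method != "permutation":
        raise UsageError(f"unknown method {method!r}")
    # Exact-null Monte Carlo: directions uniform, ranks fixed; pairs with a
    # zero difference vector have no direction and stay zero under the null.
    rng = np.random.default_rng(seed)
    active = ranks[mag > 0]
    if active.size == 0:
        return AngularTestResult(
            "moore_paired", 0.0, 1.0, int(n), int(n), "permutation",
            seed=seed, n_permutations=n_permutations,
        )
    th = rng.uniform(0.0, 2.0 * np.pi, size=(n_permutations, active.size))
    X = (active * np.cos(th)).sum(axis=1)
    Y = (active * np.sin(th)).sum(axis=1)
    null = np.hypot(X, Y) / n**1.5
    p = (1 + int(np.sum(null >= rstar - 1e-15))) / (1 + n_permutations)
    return AngularTestResult(
        "moore_paired", rstar, float(p), int(n), int(n), "permutation",
        seed=seed, n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Per-recording coordination report
# ---------------------------------------------------------------------------

def coordination_report(
    rec: EmgRecording,
    episode: "Episode | None" = None,
    alpha: float = DEFAULT_ALPHA,
    config: "object | None" = None,
) -> list[CircStatResult]:
    """Interlimb and intralimb coordination r-vectors for one recording.

    Runs the envelope/burst stage of the pipeline internally, then emits one
    CircStatResult per muscle pair: interlimb Sol-L vs Sol-R, and intralimb
    Sol vs TA on each side with a TA channel.  If ``episode`` is None the
    first rhythmic episode of the reference Sol-L train is used.
    """
    from .pipeline import PipelineConfig, _burst_trains  # late import; avoids cycle

    cfg = config if config is not None else PipelineConfig()
    names = rec.channel_names
    if "Sol-L" not in names or "Sol-R" not in names:
        raise UsageError("coordination_report requires Sol-L and Sol-R channels")
    ta_sides = [s for s in ("L", "R") if f"TA-{s}" in names]
    if not ta_sides:
        raise UsageError("coordination_report requires at least one TA channel")

    trains, _ = _burst_trains(rec, cfg)
    if episode is None:
        from .bursts import find_episodes as _find

        eps = _find(
            trains[str(cfg.reference_channel)],
            cfg.episode_max_cycle_cv,
            cfg.episode_duration_floor_s,
        )
        rhythmic = [e for e in eps if e.kind == "rhythmic"]
        if not rhythmic:
            if not eps:
                raise InsufficientDataError("no analyzable episode in recording")
            episode = eps[0]
        else:
            episode = rhythmic[0]

    results = []
    pairs = [("Sol-L", "Sol-R", "interlimb")]
    for s in ta_sides:
        pairs.append((f"Sol-{s}", f"TA-{s}", "intralimb"))
    for ref_name, test_name, pairing in pairs:
        ps = onset_phases(
            trains[ref_name], trains[test_name], episode,
            pairing=pairing, animal_id=rec.animal_id,
        )
        if len(ps) == 0:
            continue
        results.append(mean_vector(ps, alpha=alpha))
    return results
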