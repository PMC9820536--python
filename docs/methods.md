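# Methods

This note records the models, conventions and design choices behind
`emgait`, in the spirit of a package methods appendix: what is computed,
why the defaults are what they are, and what the synthetic validation does
and does not demonstrate.

## Signal chain

Raw EMG is assumed to be multi-channel, signed, unitless (no calibration is
assumed; all downstream statistics are relative), sampled at 2 kHz by
default.  The chain is:

1. **Band-pass** 100–999 Hz, 4th-order Butterworth applied
   forward–backward (`sosfiltfilt`).  Zero-phase filtering is chosen so
   burst onsets are not delayed by the filter's group delay.  The upper
   edge is clamped to 99% of Nyquist.
2. **Rectification** — full-wave (absolute value).
3. **Integration** — non-overlapping bins; the bin value is the *mean*
   rectified amplitude in the bin (not RMS, not a leaky integrator: the
   mean is the simplest reading of "integration" and keeps units linear).
   Two presets are conventional: **5 ms** bins for burst onset/offset
   marking and **50 ms** (20 Hz) bins for amplitude analysis.  The trailing
   partial bin is dropped (floor rule).  The provenance of every envelope
   (filter band, window) is recorded on the object.

## Burst detection

Interactive burst marking is replaced by a deterministic hysteresis
detector so that results are exactly reproducible:

- baseline *b* = 20th percentile of the envelope; spread *s* = median
  absolute deviation (MAD, unscaled);
- onset when a bin reaches *b* + k_on·s (k_on = 3), offset when a bin falls
  below *b* + k_off·s (k_off = 1.5);
- candidate bursts shorter than 50 ms are discarded **first**, then bursts
  separated by gaps shorter than 50 ms are merged.  Discarding before
  merging prevents isolated noise bins from being absorbed into genuine
  bursts and corrupting their onsets.

Degenerate envelopes: a constant envelope yields an empty train flagged
`flat-envelope`.  A zero-MAD envelope with real dynamic range (possible
only for essentially noise-free signals, where more than half the bins are
identical) falls back to an onset threshold at 10% of the dynamic range —
low enough that weak amplitude-modulated bursts still mark, and exact for
noise-free fixtures.

Onsets and offsets are bin-edge aligned, so detected times are quantized to
the 5 ms envelope bin; the expected widening of a detected burst is about
one bin.  The zero-phase band-pass additionally smears burst edges outward
by roughly one bin per edge (measured ≈ +7% on 150 ms bursts), which is why
parameter-recovery validation on in-band synthetic signals runs the chain
without the optional filter stage (see Limitations).

**Episodes.**  Analysis is restricted to episodes of at least 10
consecutive rhythmic bursts, or at least 10 s of irregular activity.
"Rhythmic" is operationalized as a run whose cycle-duration CV is ≤ 0.5
(the underlying convention gives no numeric criterion; 0.5 separates the
generator's jittered-but-periodic gait from aperiodic activity with wide
margin).  A greedy left-to-right scan grows runs while the CV permits;
bursts not absorbed into a rhythmic run form irregular episodes when their
span reaches 10 s.  Episodes never overlap and rhythmic takes precedence.

## Gait metrics

Cycle duration is onset-to-onset of consecutive bursts of the same muscle;
burst duration is offset − onset; peak amplitude is the maximum of the
(50 ms) envelope within the burst, so amplitudes inherit the envelope's
units.  Summaries use the sample SD (n−1), SEM = SD/√n and CV = SD/mean;
CV is reported missing when the mean is non-positive.  The unit of all
group statistics is the per-animal summary, never pooled steps.

## Circular statistics

Phases are measured per reference cycle [onsetᵢ, onsetᵢ₊₁): the test
muscle's onset at time t maps to 360·(t − onsetᵢ)/cycleᵢ degrees.  Cycles
with no test onset are skipped; cycles with several use the first and set a
multiplicity flag.  Angles are handled in radians internally and reported
in degrees on [0, 360).

- **Mean vector / Rayleigh.**  r is the mean resultant length; the
  Rayleigh p uses the standard finite-n approximation
  p = exp(√(1+4n+4(n²−R²)) − (1+2n)), R = n·r, accurate to three decimals
  for n ≥ 10.  The critical value cR is obtained by solving the same
  expression for r at the chosen α (closed form), so `coordinated ⇔ r > cR`
  is exactly consistent with the reported p.  α defaults to 0.05 and is
  configurable.
- **Watson U² (two-sample).**  Computed from the pooled-sorted
  cumulative-fraction differences, with ties handled by weighting each tied
  group once.  The default p comes from the limiting distribution
  P(U² ≥ u) = 2Σ(−1)^{m−1}exp(−2m²π²u); a seeded label-permutation p
  (default 9,999 replicates, p = (1+#{U²* ≥ U²})/(1+B)) is available and is
  used as the internal cross-check.  The permutation reference statistic is
  computed through the identical vectorized code path as the permuted
  statistics so that exact ties are counted correctly.
- **Moore's paired test.**  For paired angles (pre, post), the difference
  vectors (cos post − cos pre, sin post − sin pre) are ranked by magnitude
  and the rank-weighted resultant R* = |Σ rankᵢ·uᵢ|/n^{3/2} is computed
  (zero-difference pairs contribute a zero vector).  The null distribution
  — uniform independent directions with fixed ranks — is sampled directly
  with a seeded generator (default 9,999 replicates); an embedded
  critical-value table, derived from that exact null by 10⁶-replicate
  Monte Carlo, supports quick threshold decisions, and a large-n χ²
  approximation is available as `method="asymptotic"`.

Note that permutation p-values of a *discrete* statistic cannot be exactly
uniform at very small n (the exact permutation distribution has atoms and
ties are counted as extreme); calibration checks of Watson U² therefore use
n ≥ 20 per sample, where the atoms are negligible.

## Group battery

Between-group location tests use the classic pooled-variance unpaired
Student's t (the convention in this literature; Welch is not used).
Coordination strengths r, being bounded on [0, 1], are compared with the
Mann–Whitney test — exact null distribution when min(n) ≤ 8 and no ties,
normal approximation with tie correction otherwise.  Post-drug endpoints
are expressed as per-animal post/pre ratios and tested against 1 with a
two-tailed one-sample t.  Normality is screened with the D'Agostino–Pearson
omnibus test, which is reported "untestable" below n = 8 rather than
returning an unreliable p.  All tests are two-tailed; no multiple-testing
correction is applied (matching the source convention for this battery).

## Synthetic data generator

The generator emulates treadmill hindlimb EMG as burst trains with
controlled statistical structure, not as a biomechanical model:

- Reference Sol-L onsets: cycle lengths ~ Normal(cycle_mean, jitter),
  floored at 20% of the mean.  Default cycle 1.0 s.
- Sol-R onsets at the interlimb phase (default 180°), TA onsets at the
  intralimb phase (default 180°) relative to the ipsilateral Sol, each with
  von Mises phase noise of concentration κ (the circular-normal model that
  matches the r-vector analysis; the population r is I₁(κ)/I₀(κ)).
  κ = ∞ disables jitter, κ = 0 is uniform.
- Burst windows: duration = duty × cycle (Sol duty 0.35 — stance-like;
  TA duty 0.15 — brief swing bursts).  Within bursts the signal is
  amplitude-scaled band-limited Gaussian noise (150–400 Hz), normalized so
  its rectified mean equals the configured amplitude; with
  `carrier_band=None` a constant-magnitude 250 Hz square carrier is used
  instead, giving exact rectangular envelopes for noise-free constructions.
  Per-burst amplitudes are jittered with a configurable CV.  Baseline
  Gaussian noise is added everywhere.
- Bursts that collide after phase jitter truncate their predecessor rather
  than being dropped, so the sampled phase distribution is not censored by
  the generator itself.
- Everything is deterministic for fixed (seed, stream, animal_index); the
  ground-truth event list (onset, duration, amplitude per burst) is stored
  in the recording metadata for validation.

**Cohort presets.**  The treated preset (n = 5) uses κ = 8, cycle jitter
SD 0.05 s, Sol amplitude 1.0, amplitude CV 0.15 — strong, steady
alternation.  The control preset (n = 7) uses κ = 0.5, jitter SD 0.20 s,
TA duty 0.30, Sol amplitude 0.55, amplitude CV 0.30 — weak near-uniform
coupling, unsteady cycles, long irregular flexor bursts, weaker extensor
activity.  These values were fixed once by a design simulation of the
generative model (population r = 0.24 for κ = 0.5, well below typical cR at
15–20 cycles, versus 0.94 for κ = 8) so that the group comparisons have an
unambiguous known ground truth; they are generative conveniences, not
estimates of real-animal parameters.

**Drug transform.**  The post-drug recording is an independent realization
of the same animal with Sol amplitude × 0.45, Sol duration × 0.65, TA
duration × 2.2, TA amplitude × 0.5, and κ replaced by 0.7.  The directions
(and rough magnitudes) mimic the reported serotonergic-blockade phenotype —
weakened, shortened extensor bursts, prolonged weak flexor bursts,
collapsed coordination strength with an unshifted mean angle, unchanged
cycle — and are likewise generative conveniences.

## Validation scale

The end-to-end checks run at desk scale, chosen to exercise every stage
with comfortable statistical margins: 20-second recordings (≈ 18 step
cycles per animal), cohorts of 5 + 7 animals, 20 seeds for the
directional-reproduction and parameter-recovery checks, 10,000 replicates
for Rayleigh calibration, 2,000 replicates × 1,999 permutations for Watson
calibration, and 100 replicates for detector fidelity at envelope SNR 5.

## Limitations

- The generator produces stationary burst trains; it does not model
  treadmill-speed dependence, fatigue, motion artifacts, electrode
  cross-talk or motor-unit structure.  Passing recovery tests therefore
  demonstrates correctness of the analysis chain under its own assumptions,
  not robustness to every real-recording pathology.
- Detected burst times are quantized to the envelope bin, and the optional
  zero-phase band-pass widens bursts by roughly one bin per edge; absolute
  duration estimates carry a small positive bias (≈ 1 bin, plus ≈ 2 bins
  with the filter on).  Ratio and between-group contrasts cancel this bias.
- Onset-based phase sampling is mildly censored where the test muscle's
  bursts abut (merged bursts lose an onset): under strictly uniform phases
  the per-animal false-coordination rate is ≈ 10–12% rather than the
  nominal 5% at n ≈ 18 cycles.  This is inherent to burst-onset phase
  analysis, interactive or automatic, and is negligible at the coupling
  strengths of interest (r ≥ 0.3).
- The Moore-test critical values are Monte Carlo-derived from the exact
  null (10⁶ replicates; standard error < 0.002 at α = 0.05) rather than
  transcribed from the historical printed table.
- Whether "integration" in the original capture software was a bin mean,
  sum or leaky integrator is not documented; the bin mean is a declared
  convention here, as is the operational rhythmicity criterion (CV ≤ 0.5)
  and the hysteresis detector itself.
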