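# Methods

This note documents the models behind each module, the tunable parameters
that matter, the numerical choices, and what the synthetic data does and
does not establish.

## Synthetic trial model

A trial is built around a continuous *gait phase* θ(t) that advances by one
unit per right-foot stride. Right heel strikes sit at integer phases; the
left side is offset by a configurable fraction of a cycle (default 0.5,
perfect anti-phase). Stride intervals are

  T_k = T̄ + σ_T · z_k,   L_k = L̄ + σ_L · (c·z_k + √(1−c²)·z′_k),

where z, z′ are unit-variance fractional Gaussian noise (fGn) with Hurst
exponent H (default 0.75), so stride-time and stride-length fluctuations
share one long-memory driver with correlation c (default 0.5). Defaults:
T̄ = 1.1 s, σ_T = 0.02 s, L̄ = 1.35 m, σ_L = 0.025 m, step width 0.12 m,
duty factor 0.62, 240 s at 200 Hz (48,000 samples). The population values
are conventions, not claims — typical healthy-adult magnitudes, all
configurable.

Segment pitch angles (thigh, shank, foot) are smooth one-cycle templates —
a dominant first harmonic plus a small second harmonic — evaluated at the
cycle phase of each side. Only the phase relations and event geometry are
meant to be faithful; amplitudes are plausible, not subject-calibrated.
Note that a half-cycle shift leaves even harmonics identical on both
sides, so large second-harmonic content would pull the bilateral CRP away
from 180° even for perfectly anti-phase kinematics; template harmonics are
kept small enough that all three segment pairs stay within the anti-phase
regime.

Foot kinematics: during stance (fraction = duty factor) the foot rests at
its landing position; during swing it advances to the next landing along a
smooth monotone profile with zero end slopes, while lifting with a sin²
bump (peak 0.05 m). Feet carry constant lateral offsets of ± half the step
width; the pelvis advances at the instantaneous stride speed. Optional
additive Gaussian measurement noise (angles in deg, positions in m) and a
horizontal-plane drift of configurable rate and azimuth (vertical channels
never drift) complete the model. The generator returns a ground-truth
record (true events, stride series, landing positions, injected H, mean
speed) for recovery tests.

What the generator does *not* emulate: full 3-D body dynamics, turning
geometry of a looping track, soft-tissue artifact structure, sensor fusion
behavior, or realistic joint-angle waveforms. Tests passing on this data
establish the *chain's* correctness (detection, definitions, estimators)
under known truth — not performance on any particular real dataset.

### fGn synthesis

Exact circulant (Davies–Harte) embedding of the closed-form autocovariance
ρ(k) = ½(|k+1|²ᴴ − 2|k|²ᴴ + |k−1|²ᴴ). The circulant eigenvalues are
nonnegative for H ∈ (0, 1], so the synthesized series is exactly Gaussian
with the target autocovariance (verified against the closed form by
ensemble covariance in the tests). H = 1 degenerates to a single shared
Gaussian draw. Seeding: one master seed; independent substreams per driver
via `numpy` seed sequences.

## Event detection and gait parameters

Heel strikes and toe offs are detected per foot from the vertical
foot-position (contact) channel: hysteresis thresholds (enter contact
below 5%, leave above 20% of the lift amplitude) with a 0.25 s refractory
minimum stance, then refinement of each contact segment to the first/last
sample on the stance floor (tolerance: max of 1 µm and 4× the estimated
stance noise). On noise-free trials this recovers true events to within
one sample. When stance noise exceeds 0.1 mm the contact channel is first
low-passed at 10 Hz (zero-phase); without this, millimeter-level position
noise produces ~7 ms event jitter that visibly whitens stride-time series
and biases Hurst estimates low. Footfalls touching the trial boundary
(partial cycles) are dropped.

Parameter definitions follow the standard conventions: stride quantities
from consecutive same-foot heel strikes, steps from alternating-foot heel
strikes, step width as the unsigned distance from a heel center to the
line joining the two surrounding opposite-foot heel strikes, stance/swing
percentages normalized to the stride they start (their sum is exactly 100
by construction). Single support is defined per reference-foot (right)
cycle as the time that foot alone is on the ground — equal to the
contralateral swing time — and double support as the time both feet are on
the ground within the cycle. Average speed is the smoothed (6 Hz low-pass)
horizontal pelvis path length divided by trial time. Positions are meters
internally; the table converts to the published units (cm) at the
boundary. The 26 columns are aligned by sample index and padded with NaN
(empty CSV cells), since the natural series lengths differ by design.

## Continuous relative phase

Cycles are cut at right-foot heel strikes, resampled to 100 points (cubic
interpolation; linear inputs are reproduced exactly), centered with
x − min − range/2, and transformed with the FFT Hilbert transform after
mirror-padding 10 points per side (removed afterwards) to blunt the
finite-window bias of short segments; whole-series phase computations skip
the padding. The phase is the four-quadrant angle atan2(H(t), x_c(t)) — a
two-quadrant arctangent cannot represent anti-phase. Per-trial Φ̄ pools
all normalized points of all cycles with a circular mean (an arithmetic
mean is wrap-biased near 180°); dispersion is the circular SD. Trials with
|Φ̄ − 180°| > 20° (configurable) are flagged anomalous, mirroring the
diagnostic use of CRP for data quality.

Convention: points are pooled across cycles rather than averaged within
cycles first; for the symmetric cycle distributions produced here the two
orders agree to well under a degree.

## Largest Lyapunov exponent

Delay τ: first minimum of the average mutual information (equiprobable
binning, 16 bins), where a minimum must be the lowest value of the
±5-lag window of the lightly smoothed curve — histogram AMI is locally
jagged, and for *noise-free* deterministic signals (joint distribution on
a measure-zero curve) it is intrinsically so; any realistic noise level
regularizes it. Fallback: first drop below AMI(0)/e, then max_lag.
Dimension: false nearest neighbors (distance-ratio tolerance 15, absolute
tolerance 2 SD, threshold 1%); numerically coincident pairs (exact repeats
of a noise-free orbit) count as true neighbors.

Wolf's algorithm evolves a reference point and its nearest neighbor
(Theiler window: one dominant period) for 3 samples at a time, accumulates
log(d′/d), and replaces the neighbor when the separation exceeds 10% of
the attractor extent, preferring replacements within 30° of the evolved
separation direction (relaxing to the closest point when none qualifies).
The minimum neighbor separation is 1e-4 of the attractor extent:
degenerate (zero) separations from exact orbit repeats otherwise
contribute pure floating-point noise to the log-ratios (+0.045 nats/s on
the sinusoid benchmark). All search radii are relative to the extent, so
λ₁ is exactly invariant to uniform scaling and invariant to translation to
float precision. Reported in nats/s by default, bits/s by option; the
published comparisons in this literature are qualitative ("small positive
values"), so no absolute parameter set is canonical — every choice above
is surfaced in the API and logged by the pipeline.

Verification: |λ₁| < 0.05 nats/s on a noise-free sinusoid (theory: 0), and
agreement within 15% with an independent Benettin variational-equation
oracle on the Lorenz system (σ=10, ρ=28, β=8/3; λ₁ ≈ 0.906 nats per time
unit), computed by RK4 with per-step tangent renormalization.

## Hurst exponent

Model: x ~ N(μ1, σ²R(H)) with R from the fGn autocorrelation. With the
noninformative prior p(μ, σ²) ∝ 1/σ² both nuisances integrate out in
closed form, leaving

  log p(H|x) = −½log|R| − ½log(1ᵀR⁻¹1) − (n−1)/2 · log S²,
  S² = xᵀR⁻¹x − (1ᵀR⁻¹x)²/(1ᵀR⁻¹1),

under a uniform prior on H ∈ (0, 1). The Toeplitz quadratic forms and
log-determinant come from a Levinson–Durbin innovations recursion (O(n²),
numba-compiled), tractable for the ≤ ~5,000-sample stride series this
package targets. The posterior is evaluated on a coarse grid (step 0.01)
and refined at step 0.001 over the region within 12 log units of the
maximum — identical effective resolution to a full fine grid at a sixth of
the cost; the point estimate is the posterior median with a central 95%
credible interval. The estimator is exactly affine invariant (inputs are
standardized only for conditioning). Calibration measured by the test
suite: mean estimates 0.50/0.90/0.10 (±0.01) on white noise and
fGn(0.9)/fGn(0.1) at n = 2048, |bias| < 0.05 at n = 1024 across
H ∈ {0.3, 0.5, 0.7, 0.9}, and recovery of an injected stride-time H = 0.9
within 0.08 from ~218 detected strides end to end.

Shuffle surrogates are seeded random permutations; re-estimating H on them
should return ≈ 0.5 when the original estimate reflects genuine temporal
structure.

## Pipeline and cohort summaries

`run_validation` simulates a cohort (per-subject gait parameters drawn
once per subject; per-trial seeds derived deterministically from the
master seed and the trial key), runs detection, CRP per segment pair,
Hurst on stride-time and stride-length series (plus shuffled surrogates;
trials with fewer than 64 strides report NaN), and optionally λ₁ on
decimated thigh angles. Summaries are per trial and per subject/day (the
up-to-9 trials of a session); a subject recorded on one day only is
handled without failure. Between-day consistency is reported
descriptively — per-subject |day-1 mean − day-2 mean| and the ratio of
between-subject variance (of subject grand means) to within-subject
between-day variance — not as ICC with significance tests, since only
qualitative consistency claims are at stake. Identical configs and seed
give byte-identical outputs; the run log records the version, seed, and
every parameter used.

## Problem sizes used by tests and the acceptance script

Estimator calibration sweeps use 100 replicates of n = 2048; bias tables
25 replicates of n = 1024; cohort tests 2–3 subjects at 90–150 s trial
duration; structural and recovery tests one full 240 s trial. The
acceptance script runs one full noise-free trial (CRP) and three
100-replicate Hurst sweeps.

## Known limitations

- The generator's kinematic realism is deliberately limited (templates,
  straight-line progression, no turns); CRP/λ₁ magnitudes on synthetic
  trials should not be read as normative human values.
- The event detector assumes a contact-like vertical foot signal; real IMU
  exports would enter through the channel map after vendor preprocessing,
  and the detector's thresholds may need retuning for real lift profiles.
- Histogram AMI on noise-free periodic signals has no well-defined first
  minimum (see above); delays chosen for such inputs fall back to the 1/e
  rule and can be short.
- The Hurst likelihood assumes stationary fGn; series with strong trends
  or nonstationarity (fBm-like) are outside the model and DFA-style
  estimators are not provided.
- Wolf λ₁ depends on evolution/replacement parameters for short or noisy
  series; values are comparable across trials analyzed with one
  configuration (which the pipeline logs), not across configurations.
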