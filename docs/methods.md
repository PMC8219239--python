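# Methods

## Statistical model

The core statistic is the Pearson partial correlation with covariate
control. For variables x, y and controls z₁…z_k, both x and y are
residualized by ordinary least squares on the design [1, z₁…z_k] and the
Pearson correlation of the residuals is reported. For k = 1 this equals the
triple-correlation closed form
(r_xy − r_xz·r_yz)/√((1 − r_xz²)(1 − r_yz²)), and for k = 0 it is the plain
Pearson correlation; both identities are exercised as test oracles, along
with an independently coded normal-equations residualization and the
`pingouin` implementation.

Significance is two-tailed ("bilateral"): t = pc·√(df/(1 − pc²)) with
df = n − 2 − k referred to Student's t. Listwise deletion is applied per
analysis — any case missing a value in x, y or any control is dropped
before computation — matching the default behavior of mainstream
statistical packages for this statistic. No multiple-testing correction is
applied by default; tables flag cells at the uncorrected 0.05 and 0.01
thresholds, and a Benjamini–Hochberg adjusted column is available as an
option. The minimal legal problem is df = 1 (n = k + 3 complete cases);
constant variables raise a degenerate-input error, which correlation
tables record as annotated empty cells rather than aborting.

Rationale for controlling total brain volume: larger brains have larger
regional volumes, so raw region–severity correlations would be confounded
by head size. Partialling brain volume out of both sides removes this
shared linear effect.

## Pipeline

Experiment 1 correlates the clinical tremor score with every handwriting
feature (control: brain volume). Features with p below the selection
threshold (default 0.05) are carried, together with the score, into
experiment 2, which tests them against every region of each morphometry
family. Selection at a lower threshold is by construction a subset of
selection at a higher one. Cohort alignment intersects subject ids across
covariates, features and every ROI table, keeps covariate input order
(making alignment idempotent), logs dropped subjects, and refuses to run
with fewer than 4 shared subjects. Reports carry a provenance block
(SHA-256 config hash excluding the output directory, seed, package
version); tables are serialized with fixed 6-decimal formatting so a rerun
with the same config and seed is byte-identical.

## Kinematic features

From the raw channels (x, y, pressure, azimuth, altitude) the package
derives adjacent-sample differences Δ and ΔΔ, velocity and speed,
acceleration and its magnitude, the instantaneous trajectory angle
atan2(Δy, Δx), instantaneous movement √(Δx² + Δy²), tangential
acceleration Δ(speed)·fs, curvature radius ρ = |v|³/|v × a| and centripetal
acceleration |v × a|/|v|. Per-trial features are the mean and sample
standard deviation (n − 1 denominator, the convention of the statistical
packages this mirrors) of each series.

Numerical choices:

* Physical kinematic series (velocity, acceleration, tangential
  acceleration) are fs-scaled finite differences with per-second units; the
  named channel Δ/ΔΔ features (including std-Δp, std-ΔΔp) are raw adjacent
  differences. Pearson correlation is invariant to the constant fs factor,
  so the choice only affects units, not downstream statistics.
* Curvature radius is capped at ρ_max = 10⁶ where the cross product falls
  below ε = 10⁻¹², keeping summaries bounded on near-straight segments;
  centripetal acceleration is 0 where speed < 10⁻¹². On sampled uniform
  circular motion at fs = 100 and ω ≤ 2π rad/s the finite-difference errors
  against ωR, ω²R and R are well under 1%.
* Zero-displacement samples carry the trajectory angle forward from the
  last moving sample (0 if none); angle summaries treat the atan2 values
  as ordinary reals (no circular statistics) — a documented limitation
  acceptable for a spiral task whose heading winds monotonically.
* Instantaneous movement is defined as the per-sample displacement
  magnitude; it is the raw-difference counterpart of speed.

By default only on-surface samples contribute to summaries and differences
are never taken across stroke boundaries: the spiral is drawn on-surface,
and in-air pressure is identically zero, so including hover samples would
deflate the pressure-variability features toward the pen-lift count rather
than the tremor. `surface_only=False` (CLI `--include-air`) restores
whole-series summaries for sensitivity analyses.

## Recording format and segmentation

Recordings use an SVC-style text dialect (x y t pen_status azimuth
altitude pressure, optional leading count line, timestamps in ms). Values
are validated on read and before write: strictly increasing timestamps,
pen status in {0, 1}, azimuth [0, 360), altitude [0, 90], pressure
[0, p_max] with p_max defaulting to 2047 (11-bit quantization typical of
consumer tablets; correlations are scale-invariant so the ceiling is
cosmetic). In-air samples keep coordinates but force pressure 0. The
sampling rate is inferred from the median timestamp spacing, with a
warning (not an error) when it deviates more than 5% from the nominal
100 Hz. Stroke segmentation is run-length encoding of pen status; the
resulting half-open ranges partition the recording.

## Synthetic data

`gen_spiral` draws the Archimedean spiral r(θ) = a + bθ at constant
angular velocity (closed-form reference trajectory) and adds a radial
tremor sinusoid with per-seed random phase (avoiding phase-locking
artifacts at fs = 100) at a default 5 Hz — inside the 4–12 Hz band
characteristic of action tremor. Pressure is a baseline plus an
oscillation of amplitude gain × tremor_amplitude plus white noise, clipped
to [0, p_max]; the linear coupling guarantees that pressure variability is
strictly monotone in tremor amplitude, the property the feature set is
designed to detect. A single noise_sd drives both radial sensor noise and
pressure noise. Optional pen lifts insert in-air gaps for testing stroke
handling.

`gen_cohort` draws integer tremor scores uniformly on a wide range
(default 2–45, mirroring a severity-balanced clinical sample whose score
distribution is wide by design), Gaussian brain volumes
(1.1 × 10⁶ ± 1.0 × 10⁵ mm³, typical adult values), and one spiral trial
per subject with tremor amplitude tremor_per_level × score × a per-subject
log-normal gain (sd 0.3). The gain models inter-subject variability in
tremor expression; without it the pressure features would be an exactly
deterministic function of the score and cohort correlations would be
degenerate at 1. ROI values follow
intercept + β_level·score + β_volume·brain_volume + N(0, σ²) with
per-family default intercepts keeping volumes positive.
`plant_partial_correlation` constructs (x, y, z) as x = γz + u,
y = γz + v with corr(u, v) = ρ, so the population partial correlation
given z is exactly ρ regardless of γ; `gen_cohort` can route such a triple
through a feature column and a one-region table (affinely rescaled —
partial correlation is affine-invariant) with z mapped onto brain volume.

What the generator does not emulate: drift and re-tracing of the spiral
template, non-sinusoidal or amplitude-modulated tremor, pressure–position
coupling, device jitter in sampling times, or missing covariates. Passing
tests therefore demonstrate that the statistical machinery recovers
structure that is present, not that real tremor obeys this generative
model.

## Demonstration and problem sizes

The packaged demo uses n = 19 subjects — the scale of a small clinical
handwriting cohort — with planted couplings of roughly |pc| ≈ 0.8–0.9,
strong enough that a sample of this size detects them reliably while still
exposing small-sample p-value behavior. Calibration checks use 2000
replicates (type-I error at n = 19, observed within [0.03, 0.07]) and 100
replicates for Fisher-z coverage at n = 500; kinematics oracles use 500- to
1000-sample trajectories. The full test suite and the acceptance script
each run in seconds on one CPU.

## Known limitations

* Angle summaries are non-circular (see above).
* The curvature cap makes straight-segment summaries depend on ρ_max;
  comparisons across configurations should keep it fixed.
* The synthetic cohort couples every kinematic feature to severity through
  a single tremor mechanism, so experiment-1 tables flag many features at
  once; real data would show a sparser pattern.
* Whether real acquisitions include in-air samples in pressure summaries
  is acquisition-specific; both modes are provided and the default
  (surface-only) is documented above.
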