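# Methods

## Point-mass model and inverse dynamics

The jumper is a point mass at the centre of mass (CoM).  Three phases are
modelled.

**In-run.**  Along-track dynamics on the hill profile,

    dv/dt = g sin δ(s) − [ μ F_N + ½ ρ v² C_D A ] / m,
    F_N   = m ( g cos δ(s) + v² κ(s) ),

with arc position `s`, slope `δ` and curvature `κ` (zero on the straights,
`1/r` on the circular transition).  The centripetal term makes the normal
force — and with it friction — rise through the transition, which is the
dominant in-run force signature.

**Take-off.**  An instantaneous velocity impulse `w` perpendicular to the
motion, leaving the along-track speed unchanged (new speed
`sqrt(v² + w²)`).  A real push-off develops over roughly half a second;
the impulse is a deliberate simplification that keeps the flight initial
state interpretable.  Its one visible cost: the impulse is a velocity
step, which no 5 Hz band-limited processing chain can follow, so
chain-vs-truth comparisons exclude ±0.3 s around take-off (agreement
outside that neighbourhood is ~0.003 m/s RMS in CoM velocity).

**Flight.**  `a = −g ŷ + [ −F_D v̂ + F_L n̂ ] / m` with `n̂` the velocity
direction rotated +90°.  Drag and lift areas are the identifiable products
`C_D A`, `C_L A` (coefficient and frontal area never separate in
trajectory data); both may be constants or functions of time since
take-off.  Flight ends at the first intersection of the trajectory with
the landing profile (linear interpolation between samples); competition
distance is arc length along that profile.

Inverse dynamics reverses this: the motion angle `φ = atan2(vy, vx)`
rotates `m(a − g)` into components parallel (braking `F_b`) and
perpendicular (`F_p`) to the motion.  The printed rotation convention
yields negative values for resistive forces; `F_b` is reported negated so
that a force opposing motion is positive, which is how braking-force
curves are conventionally plotted.  In flight `F_b = F_D` and
`F_p = F_L`; in-run they are the sums `F_D + F_f` and `F_N + F_L`, which
trajectory data cannot separate — the in-run drag-area estimate therefore
bounds the true value from above (friction folded in).

## Numerical choices

* **Integrator** — classical fixed-step RK4, default 1 ms.  Energy drift
  with all dissipation off is < 1e-8 relative over a full jump; tests
  assert < 1e-6.  RK4 substeps may probe marginally outside the track
  domain near a stall; the force evaluation clamps arc position.
* **Filtering** — 4th-order Butterworth, 5 Hz cut-off, zero-phase
  (forward–backward, so the amplitude response is the squared one-pass
  magnitude and the net phase is zero), applied to raw positions and again
  before each differentiation.  Each stream is filtered at its native rate
  (50 or 60 Hz) before any resampling.  Endpoint padding is *odd*
  (point-symmetric) reflection over three filter lengths: even reflection
  flips the boundary slope and corrupts the differentiated channels for
  several hundred milliseconds at each end, odd reflection preserves it.
* **Differentiation** — central differences (one-sided at the ends),
  same-length output.
* **Drag-area inversion** — the pointwise estimate `2 F_b / (ρ v²)` is
  masked where `v` is below a 5 m/s floor or `F_b ≤ 0` (negative apparent
  drag occurs briefly after take-off; the inversion blows up at low
  speed).  For window summaries the package uses
  `2 ⟨F_b⟩ / (ρ ⟨v²⟩)` instead: under acceleration noise the positivity
  mask clips the noise distribution and biases a mean of pointwise
  estimates, whereas averaging force and speed first is unbiased.  The
  steady-flight window runs from 0.5 s after take-off to 0.3 s before
  landing (≈3 s on the bundled hill).
* **Comparison grid** — horizontal distance, [−5, 20] m at 0.1 m spacing
  (finer than either sensor's spatial step at 25 m/s); nodes outside a
  stream's support are flagged missing, never extrapolated.  Distance
  rather than time is the abscissa because the error summaries are
  reported per 5-m stretch of track.

## Body model and pose processing

Right-side sagittal landmarks (ankle, knee, hip, shoulder, elbow, wrist,
upper chest, upper neck, head top) feed a segment model with
Zatsiorsky/De Leva-style mass and CoM fractions, collapsed onto this
landmark set (foot mass merged into the shank with a distally shifted CoM
fraction; both limbs lumped onto the right-side chain) plus equipment
point masses for helmet, boots and skis.  All fractions, reference
lengths and equipment masses live in an editable parameter file
(`src/skijump/data/anthropometry.yaml`), not in code.

Joint angles are included angles: knee θ (ankle–knee–hip), hip γ
(knee–hip–shoulder); the body angle of attack ψ is the unsigned angle
between the ankle→shoulder vector and the velocity, reported in [0, π]
since it is used as a magnitude.  Angular velocities run through the same
filter→differentiate chain.

Camera self-calibration exploits length constancy: a single out-of-plane
foreshortening angle (horizontal image axis compressed by its cosine) is
chosen by bounded scalar minimisation of the summed coefficient of
variation of apparent shank/thigh/upper-arm lengths over a ≥20-frame
window, after which the pixel→metre scale follows from the athlete's
reference segment lengths.  A synthetic stream with 0.2 rad of injected
foreshortening is recovered to ~1e-7 rad; the exact parametrisation of
the image-plane rotation is a design choice, and only the product
(corrected, scaled coordinates) matters downstream.

## Statistical comparison (SPM)

Per-jump paired differences of two streams on the common grid form an
n × Q field.  The pointwise paired t statistic
`t(q) = mean(q) / (sd(q)/√n)` is thresholded family-wise using 1D Random
Field Theory: smoothness is estimated from the variance-normalised
residual gradients (`FWHM = sqrt(4 ln 2 / ⟨grad²⟩)`), and the critical
value solves the expected-Euler-characteristic equation
`P(T ≥ u) + resels · EC₁(u) = α/2` (two-sided) with
`resels = (Q−1)/FWHM`.  As FWHM → ∞ this collapses onto the pointwise
Student critical value.  Cluster p-values use the expected-extent
exponential approximation; a seeded sign-flip permutation of the maximum
|t| provides a nonparametric cross-check (agreement within ~10% for
smooth null fields at n = 16).

Calibration, measured by this package's own Monte-Carlo (n = 16 unit-variance
Gaussian fields smoothed to FWHM 15 on Q = 251 nodes): family-wise false
positive rate ≈ 0.04–0.05 at α = 0.05.  Power is governed by the ~4.1
threshold at these settings: a mean offset of 3σ/√n (pointwise
noncentrality 3) is *detected somewhere* in most replicates but almost
never produces a cluster covering ≥80% of its region; near-certain full
coverage needs roughly 8σ/√n.  Tests assert the power property at
amplitudes where it holds.

## The synthetic-data generator as study design

The generator's defaults encode the study conditions rather than
free-floating knobs:

| parameter | default | rationale |
|---|---|---|
| hill | HS106-like, K-point 95 m | transition r = 90 m, table 11°, straight 35°; usable in-run ≈ 65–85 m |
| body / equipment mass | 65 + 10 kg | light athlete plus helmet, boots, skis |
| μ (ski–snow) | 0.03 | low-friction prepared track |
| in-run C_D A | 0.22 m² | crouched position, wind-tunnel range ≈ 0.15–0.25 |
| flight C_D A / C_L A | 0.44 / 0.58 m² | L/D 1.32, within the 1.3–1.5 steady-flight range |
| take-off impulse | 2.3 m/s perpendicular | typical vertical take-off velocity |
| antenna sensor | 50 Hz, σ = 0.05 m | dGNSS-grade position accuracy |
| landmark sensor | 60 Hz, σ = 0.01 m | ≈1–2 px at ~28 m camera distance (assumption) |

These give gate-15 edge speeds of 24.6 m/s, a 0.38 m/s speed drop over
three gates, and landings at 98–102 m — a competitive jump on this hill
size.  Pose streams realise logistic crouch→flight transitions of θ, γ, ψ
exactly and are anchored to the CoM trajectory through the segment model,
so every landmark-derived quantity has an exact ground truth.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: GNSS multipath and outages (noise is i.i.d.
Gaussian, not temporally correlated), pose-estimator systematic biases
and occlusion-driven missingness, wind fields and gusts, 3D/cross-track
motion, ski aerodynamics (ski angles are out of scope), athlete-to-athlete
anthropometric variation, and a ramped rather than impulsive take-off
(a configurable ramp exists as an untested option).  Estimator accuracy
on real jumps is bounded below by these effects.

## Scoring

Distance points are affine (60 at the K-point, `meter_value` per metre);
wind compensation is a weighted mean of five along-hill wind measurements
times a hill-specific wind factor (headwind positive → negative points);
gate compensation is linear in gate steps.  The numeric factors are
configuration, not physics; the defaults (meter value 1.8, wind factor
8.0, gate factor 3.2 points/gate, uniform wind weights) are chosen
consistent with the worked example shipped in the tests, and the
between-jump decomposition (raw difference, gate adjustment, adjusted
difference) is exact arithmetic on the component points.

## Problem sizes

Default test and analysis runs use 16 synthetic jumps for the method
comparison, 100 seeded sensor-noise replicates for parameter-recovery
rates, and 1000 null replicates for SPM calibration, with the simulator
at a 1–2 ms RK4 step; these sizes were chosen so the whole suite runs on
a laptop in well under a minute per module while keeping Monte-Carlo
standard errors a factor of a few below the tolerances they check.
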