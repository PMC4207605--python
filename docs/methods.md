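# Methods

## The object and the task

The manipulated object is a planar cart-and-pendulum: a cup of mass
`m_cup = 2.4 kg` sliding on a horizontal line with a point-mass ball
`m_ball = 0.6 kg` suspended from it by a rigid massless rod of length
`l = 0.25 m` under gravity `g = 9.81 m/s²`.  It is a minimal model of
carrying a container with sloshing contents: the hand controls the cup
directly and the ball only through the cup.  The task is rhythmic — oscillate
the cup at 1 Hz between two targets — and a *strategy* is one way of doing
it, summarised by four execution variables: cup peak-to-peak amplitude `A`,
cup frequency `f`, and the ball angle and angular velocity `(θ₀, ω₀)` at a
positive cup peak.

Sign conventions: cup displacement to the right is positive; the ball angle
is measured from the hanging vertical and is positive when the ball is
displaced *opposite* to positive cup displacement, so anti-phase
coordination has `θ₀ > 0` at a positive cup peak.  The cup trajectory is
the peak-aligned cosine `x(t) = (A/2)·cos(2πft)`; `t = 0` is a positive cup
peak, which makes the simulated `(θ₀, ω₀)` directly comparable with
experimental ball states strobed at cup peaks.  With a prescribed cup
trajectory the ball obeys

    l·θ̈ = ẍ·cosθ − g·sinθ

and the hand force follows by inverse dynamics:

    F = (m_cup + 2·m_ball)·ẍ − m_ball·l·(θ̈·cosθ − θ̇²·sinθ).

### The force convention, and why the translating inertia is m_cup + m_ball

The coefficient of `ẍ` above is *not* the textbook cart-pendulum value
`m_cup + m_ball`: the equation corresponds to a cart of mass
`m_cup + m_ball` carrying a pendulum bob of mass `m_ball`.  This convention
is fixed by the task's own anchor points, which we treat as defining the
rendered hand force: at the period-1 strategy (1 Hz, 10 cm peak-to-peak,
θ₀ = 1 rad) the strobed force is constant at −4.1 N, and the neighbouring
quasi-periodic orbit (θ₀ = 0.4 rad) strobes between −6.59 and −1.37 N.
Under the textbook coefficient these values would be −2.92 N and
[−5.41, −0.20] N — shifted by exactly `m_ball·ẍ(peak)`.  All force-based
measures (strobing, MI, MSF, force jerk) and the forward model use the
anchored convention consistently, so inverse dynamics followed by forward
dynamics reproduces the prescribed cup trajectory to better than 1e-4 m
over 45 s.

One consequence is worth stating plainly: the *free* (F = 0) oscillation of
the forward model occurs at `(1/2π)·√((g/l)(1 + m_b/(m_c+m_b))) ≈ 1.09 Hz`,
while the classic two-degree-of-freedom vibration-mode analysis of the bare
object (cup mass alone translating) gives the anti-phase mode at
`(1/2π)·√((g/l)(1 + m_b/m_c)) = 1.11 Hz`.  `linear_mode_analysis`
implements the latter (conservative eigenproblem `K v = ω² M v`), together
with the maximum free-oscillation cup amplitude `2·l·m_b/(m_b+m_c) = 10 cm`
that follows from the stationary centre of mass (`F = 0` keeps the system
momentum zero) with ball excursion bounded by the rod length.  The two
mass conventions cannot be unified; both halves are implemented as stated
and tests pin each to its own prediction.

## Numerics

* Integration: adaptive RK45, `rtol = atol = 1e-8`, dense output resampled
  at 120 Hz (the experimental rate).  Simulated trials last 45 s (45
  nominal cycles) with no transient discarded; the endpoint sample is
  included (5401 samples).
* Forward dynamics interpolates the applied force piecewise-linearly and
  caps the solver step at one force-sample interval, so the integrator
  never steps across interpolation kinks uncontrolled.  At 120 Hz the
  round-trip cup-position error is ~2e-5 m over 45 s.
* Strobing picks positive cup-position maxima only (not minima), including
  closed-interval endpoint maxima: a 45 s peak-aligned 1 Hz trajectory has
  46 strobes at t = 0, 1, …, 45, of which 21 fall in the closed [25, 45] s
  analysis window.

## Strategy measures

**Mutual Information** between the continuous hand force and the cup phase
`φ = (2πft) mod 2π`, in nat.  The joint density is a product-Gaussian
kernel estimate with per-dimension Silverman bandwidths
(`h = 1.06·σ·n^{-1/5}`, n the number of samples), evaluated on a 128×128
grid spanning `[min−3h, max+3h]` in force and `[0, 2π)` in phase; phase
circularity is handled by replicating the sample at `φ ± 2π`; marginals are
obtained by integrating the joint and MI by trapezoidal summation.  Because
bandwidth and grid co-transform with the data, the estimate is exactly
invariant under affine force rescaling.  MI magnitudes from kernel
estimates of near-deterministic relations are bandwidth-dominated, so only
orderings and map patterns are meaningful, not absolute values.  Degenerate
input (constant force) returns 0 with a warning.

**Predictability Index.**  `PI = 1 − v/v_max`, clipped to [0, 1], where `v`
summarises the strobed-force scatter.  For the map surfaces `v` is the
strobed-force variance *relative to the continuous-force variance of the
same strategy* and `v_max` its maximum over the evaluated map.  The
relative form makes the index scale-free; with the raw variance instead,
large-amplitude strategies dominate the normaliser and the index loses its
concordance with the MI map (Spearman ρ drops from ≈0.6 to ≈0).

**Sensitivity.**  Maximum |ΔMI| under ±10 %-of-range perturbations of
frequency (0.04 Hz), amplitude (3.6 cm) and initial angle (π/10 rad) — not
ω₀ — expressed in units of `0.1 × (MI range over the evaluated map)`.
Values above 1 are expected in rugged regions.  Perturbations leaving the
simulable domain are skipped with a warning.

**Global Lyapunov Exponent.**  Largest finite-time exponent of the driven
ball subsystem: the tangent dynamics `u̇ = J(t)·u` with
`J = [[0, 1], [(−ẍ·sinθ − g·cosθ)/l, 0]]` is propagated along the
reference trajectory with renormalisation, separately from unit vectors
along θ and θ̇, and the larger average log growth is reported.  Finite-time
estimates carry a transient bias: for a neutrally stable (quasi-periodic)
orbit the accumulated log growth telescopes to the log of the tangent
ellipse's aspect ratio, of order `ln(ω_pendulum) ≈ 1.8`, giving a bias
`≈ 1.8/T` — about 0.03 s⁻¹ at the 60 s single-strategy default.  That is
the same size as the smallest exponents in the predictable valley of the
map, so map evaluation uses a 240 s horizon (bias ≈ 0.008 s⁻¹), and the
undriven `A = 0` neutral-stability check uses 120 s (the bound requires
`T > 1.8/0.02 = 92 s`).  Map evaluation propagates all cells and both
tangent vectors simultaneously with a fixed-step (2.5 ms) RK4, which is
what makes the long horizon affordable; single strategies use an adaptive
reference at `rtol = 1e-8`.

**Mean Squared Force.**  Time-average of `F²` over the trial (N²).

**Jerk.**  Third derivative by repeated central differences at the sampling
rate; the three edge samples on each side are dropped (one-sided
differences there would inject spurious spikes).  Raw jerk is `mean|j|`;
normalised jerk is `mean|j| / max|j|`, dimensionless and
amplitude-invariant — a pure sinusoid gives `2/π` at any amplitude and
frequency.  Ball smoothness is scored on the ball's translational
displacement `x_b = x − l·sinθ` rather than the ball angle: in-phase
coordination carries the ball smoothly with the cup while anti-phase makes
its path rough, which is the dissociation the smoothness criterion is meant
to express; angle-based variants instead minimise at the near-separatrix
boundary (large slow swings from θ₀ ≈ ±π/2), a feature of pendulum
kinematics rather than of the coordination pattern.  For chaotic cells
`max|j|` is resolution-dependent, so normalised-jerk values are
estimator-specific; the map's low-jerk plateau (chaotic and in-phase cells)
is robust but the single arg-minimum cell within that plateau is not.

**Spectral arc length.**  Arc length of the max-normalised magnitude
spectrum (zero-padded FFT) up to an adaptive cutoff: the highest frequency
below 20 Hz whose normalised magnitude still exceeds 0.05, with the
frequency axis scaled to [0, 1].  More negative = less smooth; invariant
to amplitude scaling.

## Result space

Maps are evaluated on an `(A, θ₀)` grid with `f = 1 Hz` and `ω₀ = 0` fixed
(ω₀ has little effect on the measures).  The default grid is 37×33 over
A ∈ [8, 44] cm, θ₀ ∈ [−π/2, π/2]; the test suite and examples use 20×20,
which resolves every map-level claim and completes in a few minutes on one
CPU.  Cells are simulated independently; failures leave NaN cells and are
recorded in the provenance sidecar.  Optima are grid arg-optima with ties
broken toward larger A, then larger θ₀.  Lookups interpolate bilinearly.

## Experimental-trial pipeline

Peak detection low-passes the cup channel (zero-phase 4th-order Butterworth,
10 Hz — the original filtering is unstated, so this is a documented choice)
and finds extrema separated by at least half a nominal period with
prominence at least 25 % of the running cycle amplitude, refined to
sub-sample times by parabolic interpolation.  Per-cycle execution variables:
`f_k` from successive-maximum spacing, `A_k` as peak-to-trough excursion of
the full cycle, `(θ₀ₖ, ω₀ₖ)` interpolated at each refined maximum; window
means use cycles whose strobe time lies in the closed [25, 45] s window
(asynchrony statistics use [20, 45] s).  When the ball angular velocity is
not recorded it is derived by 4th-order central differences of the
low-passed angle.  Experimental MI uses the raw continuous force against a
piecewise-linear phase (0 → 2π between successive maxima); smoothness
measures are computed on cycle-averaged profiles (each cycle linearly
time-normalised to 120 samples), isolating the intended strategy from
cycle-to-cycle variability.  Early-vs-late practice effects compare the
per-subject means of the first and last 5 trials with a two-sided paired
t-test, reported at both α = 0.05 and α = 0.10.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
any individual subject.  Per-trial target strategies follow an exponential
learning curve in amplitude (21.45 → 28.03 cm peak-to-peak, timescale 12
trials — the published group values serve as emulation targets) with
Gaussian trial-to-trial jitter; the target ball angle approaches +0.95 rad
the same way; early trials are replaced with probability
`0.2·exp(−trial/12)` by chaotic in-phase episodes (θ₀ ≈ −1.2 rad).  Trials
are realised physically: the inverse-dynamics feedforward of the target
plus a stiff proportional-derivative correction toward the target sinusoid
(kp = 1600 N/m, kd = 120 N·s/m — soft gains leave a 1 Hz tracking residual
of over a centimetre from the ball-force mismatch), a weak ball-swing
damping term (−1.0 N·s·θ̇, standing in for the stabilising corrections
human subjects apply; without it the undamped pendulum absorbs motor-noise
energy until it rotates), and white Gaussian motor noise (SD 1 N).  Sensor
noise (1 mm position, 5 mrad angle) is added to the recorded channels, and
the recorded ball angle is wrapped to (−π, π] — the coordinate on the cup's
arc; chaotic episodes can pass over the top.  Integration is fixed-step RK4
at 240 Hz, vectorised across a subject's trials and bit-reproducible per
seed (per-subject seeds derive from the cohort seed via SeedSequence).

What the generator does *not* emulate: human corrective timing structure
(the PD controller is a synthesis device, explicitly not a model of the
controller), within-trial drifts of intent, metronome-coupling dynamics
(beeps are placed on the nominal extrema), or realistic sensor artefacts.
Passing pipeline tests on these cohorts therefore shows the estimators and
statistics are correct and calibrated, not that they would be unbiased on
every feature of real recordings.

Known quantitative limits: realised trial amplitudes track the target with
a small systematic shortfall (a few mm, from residual tracking error under
noise), so cohort-level means sit slightly below the nominal learning
curve — within the ±2 SD emulation bounds the calibration check uses.  The
strobed ball angle of a free-running quasi-periodic orbit wanders around
the period-1 fixed point rather than staying at its initial value; window
means of θ₀ₖ therefore reflect the orbit's strobe distribution (≈ 1.1–1.2
rad late in practice), not the initial condition, and recovery of ball
variables is asserted per cycle against the trajectory's true strobes.

## Problem sizes used by the tests and the reproduction script

Map-level claims are checked on a 20×20 grid (45 s per cell at 120 Hz; GLE
horizon 240 s); cohort statistics on the full default 8 subjects × 50
trials; the null-calibration of the paired t-test on 1000 replicates drawn
from the generator's zero-learning target process (the physical trial layer
does not affect the test's size).  The reproduction script
(`scripts/acceptance.py`) needs only the mode analysis and two 45-cycle
simulations.
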