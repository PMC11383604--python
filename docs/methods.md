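# Methods

## Constitutive model

The package models mucus as a Burgers material: a Maxwell element
(spring `E₁ = 1/J₁`, dashpot `η₀`) in series with a Kelvin–Voigt element
(spring `E₂ = 1/J₂`, dashpot `η₂ = τ/J₂`). Its creep compliance under a
constant stress applied at `t = 0` is

    J(t) = J₁ + J₂·(1 − e^(−t/τ)) + t/η₀

with `J₁` the instantaneous elastic compliance (Pa⁻¹), `J₂` the retarded
compliance amplitude (Pa⁻¹), `τ` the retardation time (s) and `η₀` the
zero-shear viscosity (Pa·s). `BurgersParams.moduli()` exposes the
spring/dashpot view for users who prefer moduli to compliances. A
viscoelastic solid is represented by the exact sentinel `η₀ = ∞` rather
than a large finite viscosity, so the complete-recovery limit holds to
machine precision instead of approximately.

The response to the on/off step-force protocol follows from Boltzmann
superposition: each force step of size `±F₀` at time `s` contributes
`±(F₀/C)·J(t − s)`. This closed form is verified in the test suite
against direct numerical integration of the element ODEs (piecewise per
constant-force phase, `solve_ivp` at rtol 1e−12) to 1e−9 relative.

Assumptions: linear viscoelasticity (verified post hoc by the
stress-sweep check), negligible wire inertia, a single no-slip plane
below the probe, and no large-strain effects. Frequency-domain moduli
(G′/G″) and generalized Prony series are out of scope.

## Geometry and calibration

The wire is treated as a cylinder of radius `r` (default 12.3 µm) and
length `L` (5.3 mm) translating along its axis parallel to the no-slip
cell surface at center height `h` (default 57 µm, the mean measured
wire-center-to-cell-surface distance). The drag coefficient is

    C = 4πL / arccosh(h/r)

which diverges at contact (`h → r`, rejected at construction) and
decreases monotonically with height; at the default geometry
`C = 3.007 × 10⁻² m`. The far-field approximation `4πL/ln(2h/r)` agrees
asymptotically and serves as a built-in sanity check, but at `h/r ≈ 4.6`
the arccosh form is the one used.

Force–current calibration is a line through the origin by default
(`F = slope · I`), with the intercept exposed for generality. Anchoring
at (0.6 A, 110 nN) predicts 458.3 nN at 2.5 A, i.e. the nominal 460 nN
within rounding.

Wire height is measured from multi-channel z-profiles: each channel's
dominant peak is localized by a least-squares parabola over ±4 samples
around the maximum. The windowed fit was chosen over a three-point
parabola because it averages intensity noise that the three-point form
amplifies (at 10% noise the windowed fit localizes within 1 µm in ≈98%
of trials versus ≈78% for three points), at the cost of a small,
sub-0.05-sample bias on a Gaussian peak. The wire height is the
bright-field peak minus the membrane-channel peak; the particle channel
(mucus top) is reported but not used in `C`.

## Protocol segmentation

The recorded force waveform is thresholded at half its maximum and
run-length encoded into on/off windows; runs shorter than a 1 s debounce
(configurable) are merged into their predecessor, so single-sample
glitches do not split windows. A series that never turns on is a
protocol error. The default protocol is 10 s on / 20 s off, two cycles,
sampled every 500 ms; the sample exactly at a switch belongs to the off
phase (the step is taken to occur at that sample time).

## Fitting

Displacement converts to compliance via `J = C·x/F₀`. Only force-on
windows are fitted; the model is evaluated in log-parameter space
(`log J₁, log J₂, log τ, log η₀`) with Levenberg–Marquardt and analytic
Jacobians. Initialization: `J₁` from the first on-phase sample, `η₀`
from the reciprocal slope of the last third of the window, `J₂` from the
flow-asymptote intercept minus `J₁`, `τ` from the half-rise time of the
retarded component. Eight multi-starts (seeded log-normal perturbations,
SD ln 3) guard against local minima; the search ends early when a start
reproduces the best optimum or the residual is numerically zero.

Two design points matter here:

* **Force history is part of the model.** Later on-windows begin on top
  of unrelaxed flow from earlier cycles. Each window's model therefore
  includes the Boltzmann superposition of all earlier on/off steps at
  the segmented step times, rather than treating the window as a virgin
  creep test.
* **On-windows are fitted jointly.** Within a single later window the
  flow accumulated from previous cycles is exactly degenerate with a
  shift in `J₁`, so per-cycle fits determine `η₀` poorly (median
  relative error ≈17% at 2% noise). Pooling both cycles into one
  parameter vector uses the between-cycle level difference
  (`t_on/η₀` plus retarded relaxation) and brings the median `η₀` error
  to ≈1%. Individual per-cycle fits are still computed as a
  quality-control metric (their `J_e⁰` spread is flagged above 20%);
  cohort-scale runs skip the QC refits for throughput.

A fitted `η₀` above `10⁶ · t_on/J_e⁰` contributes less than a part in
10⁶ of the observed compliance; it is reported as the solid sentinel
(`η₀ = ∞`, `solid_limit` flag) instead of a meaningless huge number.

Noiseless traces are recovered to better than 1e−12 relative; at 2%
displacement noise the median relative errors of `J_e⁰` and `η₀` are
≈0.7% and ≈1.1% over 50 seeds.

## Recovery ratio and classification

For each on-window followed by an off-window,

    R = (x_end_on − x_end_off) / (x_end_on − x_baseline)

with the baseline taken as the last sample before the on-window (zero
for the first cycle — the baseline subtraction makes later cycles
comparable to the first). Last samples are used rather than extrapolated
asymptotes: simpler, robust to noise, and the closed form
`R = 1 − (t_on/η₀)/J(t_on)` (valid when the off phase spans ≳10 τ)
serves as the test oracle; sampled and closed-form values agree within
1% (the last on sample sits `dt` before the switch). `R` is clipped to
[0, 1] and averaged over cycles.

Classification: viscoelastic solid iff `R ≥ 0.9` (configurable). The
threshold operationalizes "recoils nearly completely" versus "recoils
only partially"; no quantitative criterion is standard, so 0.9 is a
package choice reported with results. Under the default synthetic
effects this separates conditions cleanly (liquid R ≈ 0.75, solid
R ≈ 0.95).

The stress-sweep check declares the linear regime when the coefficients
of variation of `J_e⁰` and `η₀` across ≥3 forces are ≤0.2 and the slope
of log J_e⁰ versus log F₀ is within ±0.1.

## Wire tracking

Frames are projected onto the wire axis with rows weighted by the
reference frame's transverse ridge profile (a matched projection —
uniform row averaging dilutes the signal with empty rows). The projected
profile is differentiated and smoothed (Gaussian, σ 1.2 px), turning the
visible wire end into a localized near-Gaussian bump, and
cross-correlated against a template cropped by the search range so every
lag has full overlap (this makes integer-pixel shifts exact). The peak
is refined by a parabola through the three samples around the maximum,
fitted to their logarithms when positive — exact for a Gaussian peak and
resistant to pixel locking. Tracking runs twice: the second pass uses
the average of all first-pass-aligned profiles as the template, which
averages the reference frame's own pixel noise down by ≈√n_frames and
removes the bias a single noisy reference imprints on every frame.
Frames whose normalized correlation peak falls below 0.5 are flagged as
failures (NaN), never interpolated.

At a per-pixel SNR of 10 the round trip (render → track) has pooled RMS
error ≈0.08 px and mean bias ≈0.01 px over 20 traces. The residual
per-trace bias floor is the localization noise of frame 0 itself, since
displacement is defined relative to that frame. Rotation of the wire and
two-wall hydrodynamic corrections are not modeled.

## Synthetic data

The generators are pure functions of their arguments and a seed.

* **Traces** — the Boltzmann-superposition response plus i.i.d. additive
  Gaussian displacement noise whose SD is `noise_sigma` times the
  recoverable plateau `(F₀/C)·J_e⁰`; 2% is the default acquisition
  noise.
* **Cohorts** — donors draw latent `(J_e⁰, η₀)` log-normally (medians
  0.15 Pa⁻¹ and 200 Pa·s, log-SD 0.3 — a moderate inter-donor spread);
  `τ = 2 s` and a 2:1 `J₁:J₂` split are held fixed. Condition effects
  multiply `(J_e⁰, η₀)`: IL-13 uses (0.3, 20) — compliance down
  three-fold, viscosity up twenty-fold, strong enough that the IL-13
  recovery ratio crosses the solid threshold, consistent with the
  reported liquid→solid transition; the published effect magnitudes
  appear only in figures, so these defaults are illustrative and the
  tests assert recovery of whatever effect is specified, not particular
  values. DTT (and the methimazole analogue) multiplies the IL-13 values
  by the inverse effect, i.e. full restoration toward control by
  default. Replicate inserts (2–3 per donor) share the donor's
  parameters and differ only in measurement noise — the minimal
  structure supporting a paired design. Forces follow the per-condition
  convention (110 nN control-like, 460 nN IL-13).
* **Z-profiles** — unit-amplitude Gaussian peaks (σ 3 µm) for the
  membrane, bright-field and particle channels on a 0.5 µm grid, plus
  optional additive noise, clipped at zero.
* **Image stacks** — the wire as a Gaussian-profile ridge (transverse σ
  9.5 px, the Gaussian equivalent of the ≈38 px wide ridge at
  0.65 µm/px) with an erf-smoothed visible end (edge σ 1.2 px, an
  optical-resolution-scale edge), displaced analytically per trace so
  sub-pixel ground truth is exact; SNR is amplitude over per-pixel noise
  SD.

What the generators do *not* emulate: drift and vibration, photobleaching,
heteroscedastic or correlated noise, within-donor insert-to-insert
biological variability, wire rotation, and mucus transport by cilia.
Passing tests therefore demonstrate correctness of the inference chain
under the stated acquisition model, not robustness to every artifact of
real recordings.

## Cohort statistics

Inserts are averaged (arithmetic mean of `J_e⁰` and `η₀`) within
(donor, condition) first; ratios are formed afterwards — the two orders
differ, and aggregate-then-ratio matches plotting one mean point per
donor. The ratio paired Student's t test is implemented as a paired
two-sided t test on `log(b/a)`:

    t = mean(log r) / (sd(log r)/√n),  df = n − 1

with the geometric-mean ratio `exp(mean log r)` as the effect estimate.
Equivalence with an independent paired t test on log values is asserted
to 1e−10. Zero-variance degenerate cases are flagged (`p = 1` for
identical vectors, `p = 0` with an exact-ratio flag otherwise). No
multiple-testing correction is applied — comparisons are reported one at
a time, and the report states this. With 4–5 donors no normality test is
attempted.

Monte-Carlo calibration of the full pipeline (simulate null → fit →
test) uses 500 null cohorts of 5 donors × 2 inserts at 2% noise:
empirical type-I error ≈0.05 (both 500-seed blocks run during
development fell in [0.04, 0.07]). The power curve is evaluated on
compliance effects {0.9, 0.7, 0.5, 0.3} with 5 donors, one insert and
10% noise — a deliberately lean design so the curve rises through
intermediate power instead of saturating at 1 — with 100 seeds per
point. These problem sizes keep the whole calibration under ~4 minutes
on one CPU while leaving Monte-Carlo standard errors (≈1% for type-I,
≈5% per power point) small relative to the effects being checked.

## Numerical choices and degenerate inputs

* Fit tolerances: `xtol = ftol = gtol = 1e−15`, max 400 function
  evaluations per start; log-parameters clipped to ±60 before
  exponentiation.
* Pure Newtonian input (`J = t/η`) drives `J₁, J₂` to numerically zero
  and recovers `η` — the Maxwell/Newtonian limits are reachable.
* A trace with no rising force edge, a flat intensity channel, a wire
  below the cell surface, or a render in which the wire leaves the frame
  each raise a specific, named error; nothing is silently repaired.
* Ties in classification at exactly `R = 0.9` classify as solid (≥).
* The acquisition grid labels the sample at a force switch as off; step
  times inferred from segmentation are therefore exact for the
  synthetic protocol and accurate to ±dt/2 for real recordings.

## Known limitations

* Per-cycle `η₀` from a single on-window is intrinsically ill-determined
  once earlier cycles have left unrelaxed flow; only the pooled fit
  should be used quantitatively.
* The recovery ratio uses last samples, so it underestimates the
  continuous-time ratio by O(dt/t_on); the classification threshold
  absorbs this at the default protocol.
* Tracking accuracy is bounded below by frame-0 localization noise;
  experiments needing absolute sub-0.05 px accuracy should average
  several pre-force frames into the reference.
* The condition-effect model is multiplicative on `(J_e⁰, η₀)` with τ
  fixed; if real interventions also shift retardation times, the
  synthetic cohorts will not show it.
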