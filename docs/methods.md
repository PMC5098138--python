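# Methods

This note documents the models, parameter choices and numerical methods
implemented in `aida`, and the scope of the synthetic-data generator. All
quantitative statements below are computed by the package and checked by its
test suite.

## 1. Transport physics (`aida.physics`)

**Gas properties.** Air viscosity follows Sutherland's law
(S = 110.4 K) anchored at µ = 1.83245×10⁻⁵ Pa·s (23 °C, 101.325 kPa).
The mean free path is scaled from λ = 67.3 nm at the same reference
conditions via λ ∝ (T/T₀)(P₀/P)(1+S/T₀)/(1+S/T). Default conditions are the
instrument's heated box, 35 °C at 1 atm; body conditions (37 °C) are
available for lung-side calculations.

**Diffusivity.** D = kT·Cc/(3πµd) with the Cunningham slip correction in
Davies form, Cc = 1 + Kn(1.257 + 0.400·e^(−1.100/Kn)), Kn = 2λ/d. At 35 °C
this gives D = 1.223×10⁻⁸ m²/s at 22 nm and 7.263×10⁻¹⁰ m²/s at 100 nm.
`ParticleSpec` restricts diameters to 1 nm–1 µm, the diffusion-dominated
regime in which sedimentation and impaction are negligible; the recorded
charge state is not used in transport.

**Absorbing-sphere kernel.** The fraction of particles still airborne in a
sphere of radius r with perfectly absorbing walls after time t is the
eigenfunction series f = (6/π²)·Σ n⁻²·exp(−n²π²Dt/r²), truncated when a term
falls below a configurable tolerance (default 10⁻¹²). For Fourier numbers
Dt/r² ≳ 0.05 the n = 1 term dominates, which is what makes recovery decay
exponentially in residence time with τ ≈ r²/(π²D).

**Tube penetration.** Diffusional penetration of laminar tube flow uses the
two-branch Gormley–Kennedy expressions in the deposition parameter
µ = πDL/Q: the three-term small-µ expansion below µ = 0.02 and the four-term
exponential sum above it. The branch mismatch at µ = 0.02 is 1.4×10⁻⁴.

**Independent oracles.** Both kernels are verified against implementations
that share no code with them: a Brownian random walk of 10⁵ particles in an
absorbing unit sphere, with a Brownian-bridge first-passage correction
exp(−d₁d₂/(D·Δt)) removing the discretization bias at the wall (agreement
within 3 Monte-Carlo standard errors at Dt/r² ∈ {0.01, 0.1, 0.5}); and a
Crank–Nicolson finite-difference solution of the Graetz
convection–diffusion problem with parabolic flow and absorbing wall
(cell-centered radial grid, ghost-cell Dirichlet wall condition, damped
implicit-Euler start-up), agreeing with Gormley–Kennedy to better than 10⁻³
over µ ∈ [0.005, 0.3].

## 2. Maneuver analysis (`aida.maneuver`)

The breathing maneuver is described by five points: start of exhalation to
residual volume (I), start of inhalation (II), start of the breath hold
(III), start of the sampled exhalation (IV) and collector closure (V).

Flow-based detection integrates the trace (trapezoidal rule) and locates the
breath hold as the low-flow plateau (|Q| < 0.05 L/s with 0.02 L/s
hysteresis, ≥ 0.3 s) containing the cumulative-volume maximum; II is the
preceding volume minimum, I the last sustained negative-flow onset before
II. Plateau runs separated by less than 0.1 s are merged so isolated sensor
spikes cannot split a hold. When valve-event timestamps are present they
override the flow-derived times — the valve, not the flow sensor, defines
when ports switch.

Derived metrics:

* **V_i** — inspired volume, the flow integral over II→III;
* **residence time** — from the half-inhaled time (cumulative inspired
  volume reaches V_i/2, sub-sample interpolated) to the mid-sample time
  (cumulative exhaled volume after IV reaches half the collector volume);
* **sample depth window** — the analyzed slice of volumetric lung depth,
  [V_c − V_a + V_d, V_c + V_d]; with the nominal collector (1.2 L), analyzed
  sample (0.3 L) and dead space (0.3 L) this is 1.2–1.5 L;
* mean leg flows, used for the instrument passage time.

Maneuvers that cannot be parsed (no plateau, no inhaled volume, exhalation
that never fills the collector) raise a rejection error; the session driver
records them in the results table rather than dropping them.

## 3. Instrument loss (`aida.instrument_loss`)

The apparatus penetration is modeled as R_instrument = A·exp(−b·D·t) with D
evaluated at the box temperature (35 °C) and t the transit time through the
instrument dead volume, t = V_dead/Q̄_in + V_dead/Q̄_ex (V_dead = 0.3 L by
default). The reference parameters are A = 1.00 and b = 2.63×10⁷ m⁻²; under
this model the penetration extremes span ≈0.95 (100 nm at fast transit) down
to ≈0.08 (22 nm at slow transit) over transit times of a few seconds.

Calibration fits (A, b) by nonlinear least squares in penetration space
(`space="log"` selects exact log-linear regression instead), seeded by a
log-linear pre-fit. The design must span at least two particle sizes and two
passage times — all records at one D·t value are rank-deficient.
Diagnostics stored with the model: residual RMS, Pearson correlation between
observations and fit, and the parameter covariance. Observed penetrations
above 1.02 trigger a counting-drift warning; above 1.1 they are rejected.

## 4. Recovery (`aida.recovery`)

The recovery equation R = (C_sample/C_reservoir)/R_instrument uses window
means of the CPC trace: the reservoir mean over the last 20 s of
reservoir-tagged samples, the sample mean over the first 10 s of
collector-tagged samples. Counting uncertainty per window is
SD = √(C/(q·T)) (q = counter flow, T = window length), propagated in
quadrature. QC: the correction is flagged `low_confidence_correction` when
R_instrument < 0.1 (22 nm at slow flows), `implausible_recovery` when
R > 1.2, and the reservoir is checked for stability (CV and fitted linear
drift each ≤ 5%).

Repeats of one condition are summarized by mean and SD; an SD above 0.011 is
flagged. Recovery-versus-residence-time points are fitted with
R(t) = R₀·exp(−t/τ) by weighted nonlinear least squares (inverse-variance
weights from counting statistics), and normalized recovery is reported at a
reference residence time of 10 s.

## 5. Forward simulator (`aida.lung_sim`)

A deliberately simple two-compartment model predicts R for a commanded
breath: a symmetric 16-generation conducting tree (Weibel-type dimensions,
generation g holding 2^g tubes sharing the flow equally) applies
Gormley–Kennedy losses per generation on each leg, and a distal airspace
sphere of effective radius r (230–470 µm across the virtual cohort) applies
the absorbing-sphere kernel over the residence time:

R_pred = P_tree(Q_in) · f_sphere(t_res) · P_tree(Q_ex),
t_res = V_i/(2Q_in) + t_hold + V_c/(2Q_ex).

In the pure breath-hold limit (negligible tree, instantaneous convection)
R_pred reduces exactly to the sphere kernel. The model reproduces the
qualitative behaviours of the measurement: ln R linear in residence time
(R² > 0.999 at 100 nm), recovery increasing in particle size over 50–100 nm,
decreasing in breath-hold time, and varying < 5% when the breathing flow is
swept from 1.2 to 10.6 L/s **at fixed residence time** (flow changes both
the tree losses and, via the convective head and tail, the residence time;
the comparison holds residence time fixed because the time-normalization
step removes exactly that effect). It is a qualitative stand-in for full
multiple-path dosimetry models, not a replacement.

## 6. Synthetic data (`aida.synthetic_data`)

The generator replaces instrument and volunteers; its defaults are the
study conditions of the simulated measurements.

* **Calibration runs** — 4 sizes × 6 syringe flows (0.14–4.58 L/s) × 3
  repeats = 72 records; observed penetration = model × (1 + N(0, cv)),
  cv = 1% by default (0.5% at pure counting-statistics level).
* **Flow traces** — 100 Hz, half-sine flow segments (tidal pre-breathing,
  exhalation to RV, RV→TLC inhalation, hold, sampled exhalation), Gaussian
  sensor noise SD 0.02 L/s, valve events embedded with independent
  uniform(±0.05 s) timestamp jitter; the realized hold duration itself
  jitters within the same budget.
* **CPC traces** — 1 Hz; reservoir-tagged until shortly after collector
  closure, then 14 s of sample-tagged readings whose mean is
  C_reservoir · R_true · R_instrument_true; counts are Poisson at the
  counter flow (1 L/min → 16.7 cm³ per sample).
* **Subjects** — `SubjectProfile` carries vital capacity, dead space,
  effective airspace radius and a physiological repeat variability
  (mean-one lognormal multiplier on R, absolute SD 0.005 by default);
  `recovery_curves` can prescribe (R₀, τ) per size directly, bypassing the
  forward model. The default cohort of seven spans radii 230–470 µm, which
  spreads 100 nm R(10 s) over ≈0.15–0.48.
* **Ground truth** (true R, residence time, instrument penetration) is
  stored separately from the traces and never read by the analysis path.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds reproduce traces byte for byte.

## 7. Session I/O and pipeline (`aida.session_io`)

A session directory holds per-measurement flow and CPC CSVs with JSON
sidecars (units, sampling rate, valve events, counter flow), a
`manifest.json`, and optionally `ground_truth.json`. Floats are written with
12 significant digits, making round trips lossless at analysis precision.
`analyze_session` runs detection → metrics → passage time → windows →
recovery → aggregation → curve fits and returns three tidy tables
(per measurement, per condition, per fitted curve). The `aida` CLI exposes
`simulate`, `calibrate`, `analyze` and `report`.

## 8. Limitations

* The forward lung model is symmetric and single-path; it ignores
  asymmetric branching, residual-air mixing, cardiogenic mixing and
  inter-regional ventilation differences. Its effective airspace radius is
  a lumped parameter, not an anatomical alveolar dimension.
* Particle charge is recorded but not used; image-charge deposition is
  neglected, which underestimates losses for small, highly charged
  particles.
* The instrument loss model assumes diffusional, flow-history-independent
  losses characterized entirely by D·t; electrostatic or turbulent losses
  would break the single-exponent form.
* The synthetic generator's noise model (Gaussian flow noise, Poisson
  counting, lognormal repeat multiplier, uniform valve jitter) is a
  simplification; real traces contain drift, baseline offsets and motion
  artifacts that the QC flags only partially emulate.
* Recovery is not a deposition fraction: no correction is made for mixing
  with residual air, so absolute R values are instrument-protocol-specific.
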