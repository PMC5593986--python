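# Methods

`spotvar` implements the spot-variation FCS analysis chain — transit
times from autocorrelation curves, the diffusion law τ_D(d²), dynamical
crossover detection, regime classification and nanodomain sizing —
together with a 2D Brownian-dynamics simulator of heterogeneous
membranes that provides fully synthetic, seeded test data for every
inference stage.  This note records the models, conventions and design
choices, and what the synthetic tests do and do not demonstrate.

## The observation model

A detection spot is a 2D Gaussian of full width at half maximum *d*
(nm), profile

    w(r) = exp(−4 ln2 · r² / d²),

so `w(d/2) = 1/2` by construction.  With this convention the 1/e² beam
radius w₀ obeys w₀² = d²/(2 ln2) and the standard 2D FCS transit time
τ_D = w₀²/(4D) becomes exactly

    τ_D = d² / (8 D ln2).

This identity is the load-bearing unit convention of the package: it
links the per-spot fit (`fit_acf`), the per-spot diffusivity
(`spot_diffusivity`), spot calibration against a reference bilayer of
known D (`calibrate_spot`), and the diffusion law below.  Internal units
are µm and s; interfaces report nm, ms and µm²·s⁻¹.

## The diffusion law, crossover, and domain size

For a spot series d₁ < … < d_n the transit times follow

    τ_D(d²) = d² / (8 D_eff ln2) + t₀.

* t₀ ≈ 0 — free Brownian diffusion; D_eff is the true D.
* t₀ > 0 — transient trapping in partitioning nanodomains.
* t₀ < 0 — gel-like obstacles or a meshwork hindering long-range
  motion while short-range motion stays fast.

`fit_line` fits τ_D on d² by weighted least squares (weights 1/se² when
every point has a standard error — covariance then treated as known —
else uniform with the covariance scaled by the reduced χ²).
`fit_crossover` searches all contiguous partitions of the d²-sorted
points (≥ 3 per side), fits two independent lines per partition, keeps
the minimum total weighted RSS (ties broken toward balanced sides), and
accepts the segmented model by an F-test; BIC for both models is
reported alongside.  Because the best partition is *selected* before
testing, the naive F-test would flag spurious crossovers at well above
its nominal level; the test level is therefore Bonferroni-divided by the
number of candidate partitions, which restores the intended
false-crossover rate (observed 0/20 on free-diffusion null runs).

The crossover length ξ is the d-coordinate of the two regime lines'
intersection when it falls inside the data span, else the midpoint (in
d) of the two boundary points; the rule that fired is recorded.  The
segments are deliberately *not* constrained to join at ξ — regime fits
are independent, extrapolations are diagnostic.

Regimes are classified by intercept significance: |t₀| ≤ k·se(t₀) (k =
2 by default) is free; significantly positive is trapped; significantly
negative is gel/meshwork.  For a negative intercept the extrapolated
line crosses τ_D = 0 at

    ω = √(8 ln2 · D_eff · |t₀|),

the domain-size estimate (with first-order error propagation from
se(t₀) and se(slope); the slope–intercept covariance is neglected).  The
estimator refuses t₀ ≥ 0, where no zero crossing exists.  t₀ is carried
in ms: with D_eff in µm²·s⁻¹ this reproduces published domain sizes of
~120 and ~97 nm from their printed regime parameters, which fixes the
unit convention.

## ACF model and transit-time extraction

Curves are fitted with the standard 2D model

    G(τ) = G₀ / (1 + (τ/τ_D)^α) + baseline,

α fixed at 1 on the diffusion-law path (anomaly is analysed in
τ_D-versus-d² space, not through α; a free-α fit is available as a
diagnostic).  Initialisation: G₀ from the smallest lag, τ_D from the
first half-decay crossing, baseline from the last decade of lags.  A
non-decaying curve is refused rather than fitted.

Two practical points discovered on simulated data:

* **Fit window.**  In a periodic box the measured G falls below the
  free-plane model once tracers have explored a box-scale area, and the
  finite-trace mean-subtraction bias depresses the tail by ≈ 2∫G/T.
  The fit is therefore restricted to lags ≤ 20× the half-decay lag
  (configurable), with a free baseline absorbing the residual offset.
  Without the window, τ_D at the largest spots is biased low by ~10%.
* **Extraction convention for multi-scale decays.**  When the decay
  mixes two timescales (trapping, hop diffusion) the single-component
  fit's τ_D depends on weighting: uniform weights give a value between
  the half-decay of the full amplitude and the slow-branch timescale.
  The package default (uniform weights) reproduces the field's regime
  signatures — elevated small-spot transit times and t₀ > 0 for
  partitioning domains, t₀ < 0 for exclusion obstacles.  A model-free
  half-decay estimator (`half_decay_time`) and per-channel
  inverse-variance weights from block statistics are provided as
  diagnostics; block weighting emphasises the slow branch and is noisier
  on 1–10 s traces, so it is off by default.

Correlators: `correlate_direct` is the brute-force linear-lag oracle
(global-mean normalised); `correlate_multitau` reproduces it exactly on
the first stage's lags and then halves time resolution per stage
(channels/stage configurable, default 16), giving quasi-logarithmic
coverage of 10 µs–seconds at O(n·m) cost.

## The membrane simulator

Overdamped 2D Brownian dynamics in a periodic square box (default edge
2 µm, dt 10 µs): per-axis Gaussian steps of variance 2·D_local·dt, with
D_local read at the current position.  Heterogeneity is built from two
minimal geometries:

* **Circular nanodomains** (non-overlapping, placed by seeded rejection
  sampling, packing refused above 50% area fraction): interior
  diffusivity D_in and boundary transmission probabilities p_enter /
  p_exit.  A step crossing the boundary is accepted with the relevant
  probability, else the particle stays — a one-parameter-per-direction
  kinetic barrier rather than a potential.
* **Square meshwork** of period L: a step crossing a lattice line is
  accepted with p_hop (one Bernoulli per step).  Note that the effective
  barrier permeability is κ ≈ p_hop·σ_step/dt up to a constant, so
  p_hop is tied to the time step; scenarios state their dt.

The free scenario short-circuits to a vectorised cumulative-sum path
(statistically identical); heterogeneous scenarios run a numba kernel
with a cell list over domains.  Randomness comes from one
`numpy.random.Generator` per simulation, consumed chunk-wise in a fixed
order, so equal seeds give bit-identical trajectories.  The time step
must satisfy √(4·D_max·dt) < min(domain radius, mesh size)/4; coarser
steps are refused with the offending scale named.  MSD uses
minimum-image unwrapping and time-plus-ensemble averaging; on free runs
it recovers D within statistical error and serves as the closed-form
oracle (MSD = 4Dt).

### Reference scenarios

`spotvar.scenarios` pins the study conditions (box 2 µm, D_out =
2 µm²·s⁻¹, tracer density 25 µm⁻², 10 µs steps unless stated):

* `free` — no structure; the null for the diffusion law.
* `trapped` — dense nanoscale binding sites (r = 40 nm, ~25% area)
  where the tracer is nearly immobile (D_in = D_out/40) with
  rate-limited entry (p_enter = 0.2) and diffusion-limited exit.  The
  bound fraction contributes a slow correlation component whose
  timescale barely depends on spot size, so the single-component fit's
  τ_D is lifted most at small spots: t₀ > 0 with an elevated apparent
  small-spot D_eff, the published trapped-regime pattern.  Numerical
  exploration showed that *slow interiors* are essential — domains with
  free interior diffusion and only kinetic boundaries (p_exit < 1)
  homogenise into a pure slope change (t₀ ≈ 0) or even tip negative.
* `gel` — larger obstacles that tracers essentially never enter
  (r = 80 nm, ~30% area, p_enter = 0.01): interstitial short-range
  diffusion is fast, long-range diffusion obstructed, so the large-spot
  chord of the convex diffusion law has t₀ < 0.
* `meshwork` — permeable square mesh (L = 150 nm, p_hop = 0.1).  This
  produces hop diffusion with D_macro/D_micro ≈ 0.6 (verified via MSD),
  but at this permeability the diffusion-law intercept is *not*
  significantly negative under any standard extraction we tested — the
  leptokurtic propagator pushes apparent D up with d and cancels the
  MSD-offset signature.  The negative-intercept regime is therefore
  demonstrated with the `gel` scenario; the mesh remains available for
  hop-diffusion studies.

### Spot placement and replication

A real spot-variation series measures every spot size at one sample
position.  The pipeline instead assigns each spot diameter its own
position on a coarse grid and redraws the domain layout per replicate —
deliberately, so that the diffusion-law points have (nearly) independent
errors, matching the WLS assumptions, and so replicate scatter averages
over domain layouts.  Transit-time standard errors are the replicate
scatter (σ/√R).  Residual shared-trajectory correlation makes the
intercept SE mildly optimistic (2σ coverage ≈ 90% rather than 95% in
null calibrations with R = 5); this is accepted and documented rather
than corrected, as the classification threshold k = 2 already allows
for it.

## Population decomposition

Per-spot diffusivities from slow/fast membrane regions are decomposed
with a two-component Gaussian mixture on log₁₀D (diffusivities are
positive and spread multiplicatively), fitted by EM with deterministic
initialisation (means at the 25th/75th percentiles, shared SD, equal
weights), convergence at Δlog-likelihood < 1e−8 or 500 iterations, and
a 1e−6 SD floor.  Component S is always the lower-D component.
Separation is scored by Ashman's D = √2·|μ₁−μ₂|/√(σ₁²+σ₂²), with > 2
reported as bimodal.  All-equal samples return a flagged
single-component fallback.  On generated mixtures the split is verified
against the generating labels and against scikit-learn's
`GaussianMixture` as an independent oracle.

## Problem sizes

Defaults keep one free-scenario condition (8 spots × 5 replicates,
131 072 samples at 10 µs) under ~15 s on one CPU; the full Brownian
null calibration (20 repeats) runs in ~4 minutes, and the hindered
scenarios use 48–56 replicates of 2.6 s traces.  These sizes are
the package's chosen study conditions; statistical tolerances in the
tests (3 SE bands, ≥ 90% coverage counts) are set by the corresponding
closed-form or replicate-scatter errors.

## What the synthetic data do not show

The simulator realises the *minimal* geometries behind the three
diffusion-law signatures.  It omits photophysics beyond optional Poisson
shot noise, detector afterpulsing, interleaflet coupling, lipid–lipid
interactions, 3D effects and instrument drift.  Passing tests therefore
demonstrate that the inference chain recovers known inputs under its own
observation model — not that a particular experimental bilayer contains
domains of a given size.  Published regime parameters enter only as
closed-form checks of the τ_D/ω algebra and as geometry templates
(e.g., a 140 nm synthetic crossover) for recovery tests.
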