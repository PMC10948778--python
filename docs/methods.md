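# Methods

## Background and model

Transient-state (TRAST) spectroscopy infers the kinetics of long-lived,
non-fluorescent ("dark") states from how the *time-averaged* fluorescence
of a sample depends on the modulation of its excitation. A rectangular
pulse train of width *w* and low duty cycle η is applied; during each
pulse, population leaks from the fluorescent singlet manifold into dark
states, so the pulse-averaged emission drops as *w* grows past the
dark-state build-up time. The observable is

    ⟨F_exc(w)⟩_norm = (1/w) ∫₀ʷ S(t) dt,

where S(t) is the probability of occupying the fluorescent manifold
(ground + excited singlet) at time *t* after pulse onset. With η ≈ 1% the
dark states relax completely between pulses, so the M-pulse average
equals the single-pulse value; `trast_curve` assumes this and logs the
estimated carry-over e^(−k_red·(w/η − w)) for the longest period.

For tyrosine under 280 nm excitation, the dominant dark state is a neutral
photo-radical Ṫyr formed by photo-oxidation with concomitant proton
transfer; triplet build-up is negligible because the triplet decays fast
(k_t ≈ 5.75 µs⁻¹) and/or oxidation out of the triplet is faster still.
Two state graphs are implemented (`photophysics.StateModel`):

* **four-state** — S0, S1, T1, Ṙ with edges S0→S1 (k01), S1→S0 (k10),
  S1→T1 (k_isc), T1→S0 (k_t), T1→Ṙ (k_ox), Ṙ→S0 (k_red);
* **two-state** — fluorescent manifold Tyr(F) ↔ radical Ṫyr, with the
  effective oxidation rate

      k'_ox = k_ox · k01/(k01 + k10)

  and the excitation-independent recovery rate k_red. The singlet factor
  k01/(k01 + k10) is the S1 occupancy after singlet equilibration but
  before dark-state build-up.

The two-state pulse average has a closed form. With λ = k'_ox + k_red and
S_eq = k_red/λ:

    ⟨F⟩_norm(w) = S_eq + (1 − S_eq)·(1 − e^(−λw))/(λw).

This is the oracle against which the generic numeric path (eigen-expansion
of the generator matrix, with the exact antiderivative ∫e^(λt)dt per mode)
is verified to ≤ 1e-6 relative. Note the average approaches its plateau
S_eq only algebraically — the (1 − S_eq)/(λw) tail — while the
*instantaneous* population S(t) relaxes exponentially; convergence checks
distinguish the two.

### Mechanistic vs. operational oxidation rate

The radical is drawn from T1 mechanistically, yet the effective rate above
acts directly against the singlet occupancy. `reduce_model` offers both
readings: mode `direct` (default; what the fitting actually uses) and mode
`via_T1`, which lumps k_isc·k_ox/(k_ox + k_t) under a fast singlet–triplet
pre-equilibrium and warns when k_ox ≤ 10·k_t. The two coincide only by
interpretation; the code keeps them separate.

## Excitation geometry

The pumping rate is k01(r) = σΦ_exc(r) with σ = 4.47e-18 cm² at 280 nm and
a Gaussian flux profile of 1/e² radius ω0 = 400 nm (an instrument
calibration input, not computed here). To avoid position-resolved state
evolution during fitting, a detection-volume-averaged rate is used:

    k̄01 = ∫ σΦ·S̄1·CEF dV / ∫ S̄1·CEF dV,   S̄1 = σΦ/(k10 + σΦ).

The collection-efficiency function (CEF) is taken as Gaussian with radii
equal to the excitation radii by default (the ratio of the two shapes, not
their absolute form, dominates k̄01); geometries: `radial_2d` (thin slab,
default), `gaussian_3d` (axial 1/e² radius z0, default 5·ω0) and a
`top_hat` reference for which the average is exact. Quadrature uses
adaptive `scipy.integrate.quad`/`dblquad` on the squared-radius
coordinate with relative tolerance 1e-10 and an error guard at 1e-4.

Useful analytic anchors (radial geometry, equal radii): in the
low-saturation limit k̄01 = (2/3)·σΦ_peak; under strong saturation the
ratio falls toward 1/2 because the flattened S̄1 weighting up-weights the
beam wings (absolute k̄01 still grows monotonically with irradiance).
`full_volume_trast` evaluates the spatially-resolved average without the
single-rate approximation (Gauss–Legendre grids, refinement-stable to
< 1e-4); at 10.3 kW/cm² the approximation deviates by ≲ 3.5% of the curve
amplitude.

## Synthetic recordings

`synthetic.simulate_recording` emulates the statistical structure of a
confocal pulse-train measurement; it is first-class, tested code, not a
fixture. Each point accumulates a fixed illuminated time T_ill (1 s
default; pulse count M_i = ceil(T_ill/w_i)), so expected signal counts at
F_norm = 1 are constant across pulse widths:

    E[counts_i] = counts_at_unity · F_norm(w_i) · (exposure_i/T_ill)
                  · (1 − bleach_per_step)^i + dark_rate.

Counts are Poisson; defaults counts_at_unity = 1e5, dark_rate = 100 per
point, bleach_per_step = 0.002 (0.2% multiplicative loss per point) are
plausibility choices for a photon-counting instrument at these signal
levels — per-point integration times and count levels are not published
for this system. Reference measurements at w0 = 50 ns (short enough that
dark-state build-up λ·w0 ≲ 1e-3) open and close each sequence and recur
every third science point. One named RNG per recording, seeded from
(master seed, scenario index) via `numpy.random.SeedSequence`; identical
seeds give byte-identical serialized recordings.

Scenario presets encode the study designs with the published rate
constants as generating truth (k_ox = 19.2 µs⁻¹, k_red = 0.0037 µs⁻¹,
k_Qred = 5.8e7 M⁻¹s⁻¹):

* `fig2a_intensity_series` — irradiances {2.0, 4.0, 7.0, 10.3, 16.0,
  22.9} kW/cm² (endpoints published; interior points a design choice),
  shared k_ox and k_red;
* `fig2b_naac_titration` — ascorbate {0, 50, 100, 200, 350, 500} µM at
  10.3 kW/cm², k_red(c) = k_red0 + k_Qred·c;
* `fig3a_cam` — calmodulin ± Ca²⁺ ± 500 µM ascorbate. The
  calcium-saturated (holo) pair shares k_red (tyrosines shielded,
  accessibility 0); the calcium-free (apo) pair gains the full
  k_Qred·c quenching (accessibility 1). The apo baseline k_red is set to
  7.4e3 s⁻¹ (2× the free-tyrosine value) to encode, qualitatively, the
  observation that the radical population is lower in the apo form even
  without reductant; the readout therefore never pools dark fractions
  across conformations.

What the generator does *not* emulate — and hence what passing tests do
not establish for real data: diffusion of molecules through the detection
volume during long pulses (which biases rates at the highest irradiance),
detector afterpulsing and dead time, photon arrival-time structure,
background other than a constant dark rate, and any non-exponential
bleaching.

## Preprocessing

Dark counts are subtracted per point (clipped at zero; clipping counted).
Bleaching drift is corrected from the reference trace. The default
estimator fits log(reference rate) linearly in acquisition index — exact
for a constant per-step multiplicative loss, i.e. for the generator's own
drift model — and divides each point by the fitted level. Pooling all
references keeps the normalization noise at ~1/√n_ref of a single
reference's, and the remaining level uncertainty is a two-parameter error
whose Cholesky factor is exported in the curve metadata
(`drift_cov_factor`). Alternative drift modes `interp` (linear
interpolation between references) and `spline` (monotone PCHIP) are
available; in those modes the per-point error follows the plain counting
formula sem/f = sqrt(1/N_w + 1/N_w0). The choice matters for inference:
interpolated drift factors inject each reference's shot noise coherently
into groups of neighbouring points, which a diagonal weighting cannot
represent and which empirically inflates fitted-parameter z-scores to
std ≈ 1.7; the parametric estimator with whitened fitting (below) brings
them to ≈ 1.1.

Normalization anchors F_norm = 1 at the w0 reference level; the residual
true dark-state build-up at w0 (≈ λ·w0/2 ≈ 2e-4 at study rates) is *not*
subtracted from the data — instead the fit model renormalizes itself by
its own value at w0, so the convention cancels exactly.

## Fitting

`fitting.fit_global` fits one or many curves with each rate designated
global, per-curve, or fixed; the default mirrors the study analysis:
two-state model, k_ox global, k_red per curve, σ and k10 fixed. k10 is not
published for this system; the default 2.941e8 s⁻¹ (3.4 ns tyrosine
fluorescence lifetime, literature-typical) is exposed as configuration,
and because fitted k_ox trades off against k10 through the effective-rate
relation, fitting both simultaneously is refused unless explicitly
overridden.

Optimization runs on log10 rates (they span ≥ 4 decades) with
`scipy.optimize.least_squares` (trust-region reflective, ftol 1e-12,
xtol 1e-14, gtol 1e-10), bounds k_ox ∈ [1e2, 1e10] s⁻¹ and
k_red ∈ [1e0, 1e7] s⁻¹, initial values 1e7 and 1e3 s⁻¹, and 5 seeded
log-uniform multistarts (all starts logged; best cost returned).
Per-curve k̄01 values are cached — they depend only on fixed quantities
during a fit.

Residual weighting: when the preprocessing metadata carries the
normalization-error factor, each curve's residuals are whitened by the
Cholesky factor of Σ = diag(f²/N) + (f∘U)(f∘U)ᵀ (shot noise plus
correlated level error); otherwise they are divided by sem. Standard
errors come from the Gauss–Newton covariance of the whitened problem,
scaled by the reduced chi-square and back-transformed from log space.
Measured calibration on the intensity-series scenario: z = (k̂_ox −
k_ox)/SE has std ≈ 1.1 over 50 seeds, and the 3-SE interval covered the
generating value in 50/50 trials. A residual-resampling bootstrap
(resampling the whitened residuals and re-coloring them per curve) is
available as a cross-check and agrees with the covariance errors within a
factor of two on well-conditioned fits.

Reported uncertainties are per-fit standard errors; where several
measurement series are combined, the seed-ensemble standard deviation is
the analogous summary.

## Readouts

* **Titration slope** — error-weighted linear regression
  k_red(c) = k_red0 + k_Qred·c with closed-form WLS; parameter errors
  derive from the stated per-point errors, fit quality reported as
  chi²/dof.
* **Dark fraction** — equilibrium radical occupancy
  k'_ox/(k'_ox + k_red), the depth of the TRAST decay plateau.
* **Conformation contrast** — for one conformation, Δk_red between the
  ±reductant pair with propagated error. Verdict rule (an
  operationalization of the qualitative published contrast): *exposed* if
  Δk_red > 3·err(Δ); *shielded* if |Δk_red| ≤ 3·err(Δ) **and** err(Δ) is
  below a resolvability ceiling (default 5e3 s⁻¹ ≈ k_Qred·100 µM — above
  it, a null result cannot exclude a titration-scale effect and the
  verdict is *indeterminate*). Threshold and ceiling are reported with
  every verdict.

## Numerical choices and degenerate inputs

* λ = 0 (no dark pathway): the closed form returns F_norm = 1 exactly.
* (1 − e^(−x))/x is evaluated via `expm1` and switches to its limit below
  x = 1e-12.
* The eigen-expansion self-checks probability conservation (1e-9) and
  falls back to scaled-squaring `expm` for defective or near-defective
  generators (e.g. decay chains with equal rates, whose eigenvectors
  become parallel), also guarded by an eigenbasis condition limit of 1e12.
* Dark-count subtraction clips at zero; more than 20% clipped points
  raises a signal-to-noise warning. Reference factors outside [0.3, 1.5]
  raise a gross-drift warning.
* Curves are validated on construction: strictly ascending w, positive
  F_norm, and F_norm ≤ 1 + 5·sem (a 5σ guard — ordinary shot noise
  reaches 3σ routinely over thousands of points).

## Problem sizes used in tests and the acceptance script

Pulse-width grids of 30 log-spaced points over 100 ns – 10 ms (the study's
range; the lower bound's unit is inferred from the curves' time axis),
6-curve scenarios, 100-seed calibration ensembles, 20-seed titration and
conformation ensembles, and 20 random parameter sets for the
forward-model oracle. These sizes make the statistical claims testable at
interactive runtimes; all are parameters, not constants.

## Known limitations

* Only the two-state topology is fittable; the four-state model is
  available for forward simulation and model reduction (no k_isc value is
  published for tyrosine, so four-state use requires a user-supplied
  rate).
* Diffusion recovery through the detection volume is not modelled; fits
  of real data at the highest irradiances inherit the corresponding bias.
* The importer for the study's deposited raw data is a stub: the
  deposit's on-disk layout is not documented in the text, so the mapping
  must be supplied by whoever has the files
  (`io.register_importer`).
* pH dependence of the radical, rotamer dynamics (nanosecond scale) and
  quantum-chemical rate estimation are out of scope.
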