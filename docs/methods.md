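# Methods

## Scope and data model

`chitkin` analyzes long-format plate-reader time series (time in seconds,
well, signal in arbitrary fluorescence or absorbance units) joined to a
plate layout that assigns each well a role (sample, standard, positive /
negative / enzyme-free control), a construct, an initial substrate
concentration and an enzyme concentration in nM. Substrate concentrations
are µM for soluble oligomeric substrates and % w/v (grams per 100 mL of
suspension) for colloidal chitin.

## Progress-curve model

Each well is fit by nonlinear least squares to

    signal(t) = Σᵢ Aᵢ (1 − e^(−k₁ᵢ t)) + m·t + B ,   k₁ᵢ > 0,

with unbounded amplitudes: loss-of-signal assays (clearance, absorbance
drop) simply fit with negative A, keeping a single code path. Fits are
unweighted; no per-point variance information exists for this kind of data.

**Initialization.** Exponential fits are initialization-sensitive, so the
starting point follows a fixed, data-driven rule: B₀ = first signal,
A₀ = last − first, k₁₀ = 2/t_half with t_half the time at which the signal
first crosses the midpoint of its first and last values (the final time
point when it never does). Three starts at k₁₀ × {0.2, 1, 5} are run and the
best sum of squares wins; with several components, successive components
start 10× slower than the previous one. This makes the fit deterministic
given the data.

**Initial rate.** v₀ = Σᵢ Aᵢk₁ᵢ + m, the model derivative at t = 0, with a
delta-method SE from the full parameter covariance. On noiseless
integrated-MM curves with S0 ≤ Km/10 this v₀ reproduces the analytic
Vmax·S0/(Km+S0) to within 5%; at higher saturation a single-exponential fit
overestimates v₀ by up to a factor (1 + S0/Km) when the curve runs to
completion, which is the main driver of the few-percent downward Km bias
seen in end-to-end recovery (well inside the validation tolerances).

**Degenerate curves.** A well whose total signal excursion is within what
pure noise would produce — the expected range of n i.i.d. Gaussian draws,
≈ 2σ√(2 ln n), plus half a σ of slack per tail — is flagged
`rate_indeterminate` rather than returned as a spurious amplitude×rate
product. Non-convergence is likewise a flag, never a silent NaN.

**Residual structure and model growth.** Lack of fit is diagnosed with a
one-sided Wald–Wolfowitz runs test on residual signs: too few sign runs
means systematic structure. The null distribution is computed exactly
(combinatorially) up to 100 signed residuals and by a normal approximation
with continuity correction beyond; fewer than 8 nonzero residuals is
inconclusive. The default significance threshold is p < 0.01 and is exposed
in the assay configuration. `auto_fit` starts with one component and, while
residuals are structured, adds either a linear term — tried first when the
residual tail drifts linearly with low curvature, the signature of a
pseudo-zeroth-order excess-substrate regime — or a second exponential, up
to a configurable maximum (default 2 components). It returns the first
unstructured fit, else the best-AICc model flagged `structured_residuals`.
ΔAICc between candidate models is reported in the diagnostic.

## Calibration

Standard curves are ordinary least squares of signal on concentration,
restricted to each assay's linear range: 50 µM (4MU fluorophore), 0.5 % w/v
(OD₆₈₀ vs chitin suspension), 250 µM and 30 µM (chitobioside standards for
the ferricyanide and chitO readouts). Points exactly at the ceiling are
retained — the inclusive/exclusive choice is unobservable at these ranges
and inclusivity keeps a printed "50 µM" standard usable. The intercept is
free; rates convert through the slope alone, since the intercept cancels in
d/dt. No nonlinear (quench/saturation) calibration is modeled.

## Michaelis–Menten stage

Rates from all usable wells of a construct enter the fit jointly — no
pre-averaging of replicates — as v = Vmax·S/(Km+S) with positivity bounds,
by nonlinear least squares (unweighted). kcat = Vmax/[E] with the nM→µM
conversion handled internally. When the fitted Km runs beyond 5× the
largest assayed concentration, Km and kcat are individually unidentifiable;
the fit is flagged and only the first-order efficiency Vmax/Km (from the
origin-constrained linear fit) — hence kcat/Km — is reported.

kcat/Km's SD uses the delta method with the full (Vmax, Km) covariance.
The covariance term matters: Vmax and Km estimates from one rate series are
strongly positively correlated, and in the limit of equal relative errors
with correlation +1 the ratio's SD is exactly zero. The delta approximation
was checked against 10⁶-draw Monte-Carlo propagation (within 5% at the CVs
these fits produce).

Fold changes between constructs are reported as mutant/reference rounded to
two decimal places, matching the precision of published fold-change tables.
The attached p-value is a two-sided z test on the difference,
z = (m − w)/√(SE_m² + SE_w²); published tables do not name their test, so
this is an interpretation, and p-values are omitted when an SE is missing
or non-positive.

**Units bridge.** Bulk and oligomeric Km live on different scales; the only
sanctioned conversion is % w/v → monomer molarity via the 203.21 g/mol
N-acetylglucosamine unit mass under the infinite-polymer approximation (one
potential binding site per monomer): 0.03 % w/v ≈ 1.48 mM.

## Assay pipelines

* **four_mu** — calibrate (≤50 µM), relaxation-fit each well, v₀/slope →
  µM/s, MM fit (Km in µM).
* **clearance** — calibrate OD₆₈₀ (≤0.5 % w/v), subtract each curve's
  initial state, fit the negative-going relaxation, rates in % w/v/s
  converted to molar product rates through the monomer mass for kcat.
* **ferricyanide** — endpoint assay: rate = (max − min signal) divided by
  the *chitinase incubation time* (default 18 h), not the ferricyanide read
  window; calibrated against chitobioside standards (≤250 µM).
* **chito** — subtract the enzyme-free control matched by substrate
  concentration (the wash-dependent background drifts with time and scales
  with chitin load), relaxation-fit, calibrate (≤30 µM), MM fit with Km in
  % w/v.

Wells flagged rate-indeterminate are excluded from the rate series; if
every well of a construct is flagged (e.g. a dead enzyme), no MM fit is
attempted and the construct is reported `no_fit`. Enzyme concentration is
taken per well from the layout; when wells of one construct differ in [E],
rates are normalized to v/[E] before fitting, so Vmax of the normalized fit
is kcat directly.

Screen normalization: raw activity is the fitted v₀ of each well
(rate-indeterminate wells fall back to the whole-trace least-squares slope,
a noise-level number), and score = (activity − mean neg)/(mean pos − mean
neg), strictly per plate.

## The simulator

All validation data come from the integrated Michaelis–Menten rate law
Km·ln(S0/S) + (S0 − S) = Vmax·t, evaluated in closed form with the Wright
omega function (the overflow-safe Lambert-W form) and cross-checked against
stiff ODE integration to ~1e−11 relative error. Product maps to signal per
assay mode: gain (4MU), loss-of-scattering (signal tracks remaining
substrate), endpoint absorbance drop (signal falls by the calibrated
product equivalent), and coupled gain with a linear-in-time enzyme-free
background drift. Noise is additive i.i.d. Gaussian on the signal — the
simplest model consistent with the unweighted fits downstream. Identical
spec + seed reproduces bit-identical output.

Insoluble substrate is treated as a well-mixed pseudo-concentration obeying
MM kinetics, with one detected reducing end (1 µM product) per
2.0321 × 10⁻⁵ % w/v of monomer consumed; there is no model of
crystallinity, decrystallization, processivity, photobleaching or
inner-filter effects. Passing recovery tests therefore show the *analysis*
is faithful, not that real colloidal-chitin data obey MM kinetics.

**Reference conditions.** The validation plates mirror the assays'
operating points: 4MU — 10 nM enzyme, 8-point halving dilution from 433 µM,
1-min reads for 1 h; chitO — 5 nM final enzyme, 12-point halving dilution
from 2 % w/v spanning the assay's working range, 1-min reads for 16 h, with
one enzyme-free control per substrate concentration; ferricyanide — 1 nM
enzyme for 18 h (dilute enough that endpoint rates still track initial
rates at the lowest substrate concentrations); screening — 0.25 nM enzyme
(spent-media levels) at 10.8 µM substrate, keeping wells in the
low-depletion regime where fitted v₀ is proportional to specific activity.
Plate noise is set to 5% of the smallest well's noiseless signal span, so
every well carries at most 5% relative noise. Replicate counts are a free
parameter (default 1); no published replicate scheme exists to emulate.

## Numerical choices and limitations

* Nonlinear least squares runs through lmfit's trust-region-reflective
  backend with analytic-free Jacobians; covariances are the standard
  Gauss–Newton estimates at the optimum.
* The relaxation fitter was cross-checked against an independent
  profile-grid + 1-D-polish fitter (linear solve for A, B at fixed k):
  agreement to 4 significant figures in k₁ on seeded noisy instances.
* The fitting window defaults to all points; no cap is imposed on long
  reads.
* Tie-breaks: the multi-start winner is the strictly smallest SSE (first
  start wins ties); model growth stops at the first unstructured fit.
* Not implemented by design: substrate-inhibition / Hill / cooperative
  models, global multi-curve mechanistic fits, direct Km extraction from a
  single progress curve, vendor binary formats, and any physical model of
  chitin crystallinity.
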