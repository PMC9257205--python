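# Methods

This note documents the model, its numerical treatment, the synthetic-data
generators and the design choices that were genuinely open, in the package's
own terms.  Nothing here states an empirical result that the test suite or
the acceptance script does not itself compute.

## Two-stream radiation transfer (`optics`)

The mesophyll is a plane slab whose depth coordinate is cumulative
chlorophyll `c ∈ [0, Chl]` (µg cm⁻²), `c = 0` at the adaxial mesophyll
surface and increasing downward (fixed project-wide).  Downward/upward
diffuse fluxes obey

    dI_d/dc = −(k_s + k_a) I_d + k_s I_u
    dI_u/dc = +(k_s + k_a) I_u − k_s I_d

with boundary coupling through the epidermis: `I_d(0) = (1 − r_e) + r_i
I_u(0)` and `I_u(Chl) = r_i I_d(Chl)` for unit incident diffuse flux.  The
constant-coefficient system is solved in closed form with eigenvalue
`γ = √(k_a (k_a + 2 k_s))`; the growing mode is carried as
`exp(γ(c − Chl))` so arbitrarily large optical depths cannot overflow.
Two degenerate branches are handled analytically: the pure absorber
(`k_s = 0`, decoupled Beer–Lambert streams) and the conservative scatterer
(`k_a·Chl·(1 + k_s·Chl) < 1e−9`, linear flux profiles).  Flux balance gives
the exact identity `R + T + ∫ k_a (I_d + I_u) dc = 1`, which the tests
check against an independent `solve_bvp` oracle to 1e−6.

**Diffuse Fresnel reflectances.**  `r_e` (air→epidermis) and `r_i`
(epidermis→air) are hemispherical, cosine-weighted averages of the
unpolarized Fresnel reflectance, computed by composite 64-point
Gauss–Legendre panels (~10⁴ nodes total).  For the internal side the
integral is split at the critical angle and the total-internal-reflection
cap is added analytically, so the quadrature never sees the kink.  The
implementation satisfies the radiance-invariance identity
`1 − r_i = (1 − r_e)/n²` to better than 1e−6.  Reflectances are computed
per wavelength from `n(λ)` (with caching for the common constant-`n` case);
computing them once from a band-average `n` is an equivalent option the
default does not take.

**Inversion.**  `invert_RT` recovers `(k_s, k_a)` from bulk `(R, T)` by a
damped Newton iteration, vectorized over wavelengths, with finite-difference
Jacobians, nonnegativity projection and the Beer–Lambert initialization
`k_a0 = −ln T / Chl`, `k_s0 = max(R − r_e, 0)/Chl`.  The transmittance
residual is taken on the log scale: absolute residuals cannot condition
`k_a` for optically deep leaves (`T ~ 1e−11`), while log residuals keep the
coefficient round-trip at 1e−6 regardless of depth.  Stragglers fall back
to bounded least squares; physically inconsistent pairs (`R + T ≥ 1`,
`R < r_e`) raise errors naming the violated constraint.

**Synthetic spectra.**  A parametric generator stands in for a full
leaf-optics forward model: per-pigment absorption assembled as
`Chl·a_chl(λ) + Car·a_car(λ) + LMA·a_dm(λ)` (LMA converted g m⁻² →
µg cm⁻²), with Gaussian bands (chlorophyll Soret 430 nm and red 678 nm
peaks, a 625 nm shoulder and a low green-gap floor from pigment packaging;
carotenoid bands at 450/482 nm; weak flat dry-matter absorption), a
flat-spectrum scattering term scaled by a `structure` parameter and leaf
dry mass, and a constant refractive index 1.4.  The band magnitudes were
calibrated once against two published constraints: the step-change cucumber
leaves must reproduce the documented clamping pattern (the lower capacity
limit active only in the constant-low-light treatment), and the effective
extinctions of the spinach/eucalyptus leaves must fall in the published
per-leaf range (~0.10–0.25 per (µg cm⁻²)^p2).  A CSV hook
(`wavelength_nm,a_chl,a_car,a_dm,n_refr`) accepts measured coefficient
tables; water and dry-matter absorption are merged into the single `a_dm`
term by default (both are photosynthetically ineffective here).  The
`seed` drives a small lognormal jitter (sd 0.05) of the structural
scattering, emulating leaf-to-leaf anatomical variability; `jitter_sd=0`
gives the deterministic mean leaf.

## Broadband profile and stretched exponential (`profile`)

Per-wavelength profiles are collapsed with a bundled nominal D55 daylight
distribution (10 nm table, interpolated and renormalized on the working
400–700 nm grid; the exact SPD is not load-bearing).  The broadband
absorption coefficient is the incident-flux-weighted mean of `k_a(λ)` with
each wavelength's absorption partitioned across pigment classes in
proportion to their contribution to total absorption, scaled by
photosynthetic effectiveness (chlorophylls 1.0, carotenoids 0.7, other 0.0);
an absorbed-flux weighting is available (`ka_weighting="profile"`).

The incident profile `I(c) = Σ w(λ)(I_d + I_u)` is fitted by unweighted
least squares to `p1·exp(−k c^p2)` on the solver's `c` grid (the broadband
`k_a` enters as a separate multiplicative factor, so fitting `I(c)` or
`k_a·I(c)` gives identical `(p1, p2, k)`).  Because `I(c)` is a mixture of
spectral decay rates, the stretched exponent comes out below 1 for real
leaves; `p2` is fixed at 0.664 for all pipeline and surrogate work, with
the unit/acceptance tests confirming the free-`p2` fit beats the plain
exponential across a population.  Units of `k` are per (µg cm⁻²)^p2 and
are only meaningful together with the `p2` they were fitted with.

## Trait surrogate (`surrogate`)

Targets are `p1·k_a`, `k` and the broadband transmittance `T` (`p1` alone
is poorly identified from bulk traits; only the product matters
downstream).  One Gaussian-process regressor per target: standardized
features, anisotropic RBF kernel with automatic length scales, a white-noise
term, normalized targets, deterministic seed.  Held-out R² comes from
5-fold cross-validation before the final fit on all rows.  Training rows
pass a 5th-percentile filter on Chl (and on leaf water when present).  The
fixed measured-leaf anchor rows appended to generated populations are
application targets of the surrogate — they are excluded from training by
default, and predictions outside the training trait ranges set an
`extrapolated` flag with a warning rather than failing.

## Electron transport (`etr`)

The non-rectangular hyperbola is evaluated as
`J = 2xy / (x + y + √((x − y)² + 4xy(1 − θ)))` with `x = φ·I_a`,
`y = J_c,max` — a fused discriminant that avoids cancellation near
`x ≈ y, θ → 1` and reproduces the Blackman `min(x, y)` exactly at `θ = 1`.
Rates per unit chlorophyll (mmol e⁻ (mol Chl)⁻¹ s⁻¹) convert to leaf-area
rates with a chlorophyll a+b molar mass of 900 g mol⁻¹ (configurable; the
choice only rescales the `J_c,max` parameter family consistently).  At the
defaults, a capacity floor of 161 with Chl = 40 µg cm⁻² corresponds to
≈ 71.6 µmol e⁻ m⁻² s⁻¹ at leaf scale — the documented unit-audit corridor.

Whole-leaf integrals use 64-node Gauss–Legendre quadrature with the
integration domain split at the depths where the capacity clamps switch
(located by sign-change scanning plus Brent refinement), so every panel is
smooth; agreement with a 10⁵-point Riemann sum is required to 0.1%.  The
vectorized fitting kernels (`jleaf_batch`, `capacity_integral_batch`) use
plain 96-node quadrature without splitting — the kink error is orders of
magnitude below observation noise — and are cross-checked against the
scalar path.

The measurement side (`w_u,m`, measurement PPFD, extinction `k`) and the
growth side (`w_u,g`, `I*`, `k′ = p3·k`) are kept strictly separate:
changing the cuvette geometry never changes `V_cmax`.  The cuvette
correction `w_u,m = 1/(1 + T·r_ch)`, `I0′ = I0 (1 + T·r_ch)` uses the
leaf's broadband transmittance and a chamber-wall reflectance of 0.5, and
is applied per leaf.  The bulk-leaf identity relating apparent quantum
yield to absorptance and non-photosynthetic absorption is documentation
only: both effects are already carried by `I_a`.

## Acclimation drivers (`acclimation`)

The phenology response is a trapezoid with cardinal temperatures
(10, 28, 32, 48) °C — tomato-typical values, configurable — accumulated
hourly from leaf appearance into `PR_sum`.  The intercepted-light average
uses hours with `I0 > 1 µmol m⁻² s⁻¹` (threshold configurable) over the
`d` whole days ending at the end of the previous day, equally weighted;
an exponential-decay day weighting is available as an option.  The aging
limits are `J_c,max,mn = max(0, p_J0 + age_sign·p_J1·√PR_sum)` with
`age_sign = −1` by default: the lower limit declines monotonically with
age, which is the behaviour the whole framework is built to capture (the
`+1` variant is supported for completeness).  `p_J1` is interpreted per
√hour of accumulated response.

`simulate_timecourse` holds traits, PPFD and temperature constant, derives
the leaf's optical parameters from the trait pipeline, sets
`I* = p_i1 · I0` (steady-state light acclimation) and reports, per day, the
ontogenetic limits, the unclamped light-set capacity range, the realized
mean rate per unit chlorophyll at the growth light, and `V_cmax`.  Two
regimes emerge and are asserted by the acceptance tests: at low PPFD the
lower limit binds the whole profile, so `V_cmax` equals the limit-set value
exactly and the realized rate declines onto the limit (agreeing within 5%
where the limit is last active — the non-rectangular hyperbola keeps the
rate up to ≈ 16% below the binding minimum right at the crossover, which is
why "tracking" is asserted at the end of the binding window rather than at
its onset); at high PPFD `V_cmax` is light-set and nearly constant, and
stays within 5% over the ten days following the first engagement of the
declining upper clamp.

## Canopy computations (`canopy`)

The overlying leaf-area index counts both leaves of every layer strictly
above the target plus one leaf of the target layer, divided by the ground
area per plant (4167 cm²); layers are ordered top-down.  Chlorophyll from
four-band remission readings uses the published calibration
(57.74·(R713−R709)/(R703−R699) − 18.11), with negative results clamped to
zero with a warning and degenerate denominators rejected.  Vertical profile
smoothing uses iteratively reweighted least squares with Tukey bisquare
weights at the conventional tuning constant 4.685 (statsmodels RLM).  The
expansion-light adjustment of the Chl profile adds
`m·(PPFD − mean)·2·max(0, z − 0.5)` with `m = 0.0447`, continuous at
mid-canopy.  The LMA profile is a configurable monotone exponential
saturation anchored at the bottom-leaf value — the published empirical
curve is not reproduced; only its anchoring and monotonicity are.  The
gas-exchange conversion assumes day respiration at half the dark rate and a
CO₂ compensation point of 42.75 ppm.

## Calibration (`calibration`)

All three workflows are bounded trust-region least squares
(`scipy.optimize.least_squares`) with multistart (best of several perturbed
starts, deterministic seed), linearized (Jacobian) 95% confidence intervals
mirroring the reporting style of the field, and explicit records of which
parameters were held fixed.

* **Capacity-profile scaling:** only `p3` is identifiable from a normalized
  profile (`I*` and `p1·k_a` cancel); flat profiles raise a
  not-identifiable error.  A pooled fit averages per-profile estimates.
* **Light response:** joint fit of `(p_i1, p_i2, θ, J_c,max,mn)` over all
  step-change curves with `φ`, `p3`, `w_u,g` fixed and no upper clamp;
  fewer than two distinct transitions make `p_i2` non-identifiable.
* **Canopy series:** joint fit of `(p_i1, p4, p_J0, p_J1)` on stacked
  J_max/V_cmax residuals with equal weights (configurable), for each
  averaging depth `d` in a 1–7 grid; the `d` minimizing total SSE is
  selected and the full SSE-by-`d` profile is reported, along with
  per-stream RMSE, variance explained, and the fraction of observations
  whose capacity profile is constrained from below by the ontogenetic
  limit.

## Synthetic data (`synth`)

The generators define the study conditions and record their generating
truth.

* **Leaf population:** log-normal Chl (median 42 µg cm⁻², log-sd 0.32,
  clipped to [15, 80]) and LMA (median 45 g m⁻², log-sd 0.55, clipped to
  [15, 250]) with Gaussian-copula correlation 0.5; Chl:Car uniform in
  [4, 6]; a leaf-water column proportional to LMA used only by the
  percentile filter.  Seven measured leaves (two spinach, one eucalyptus,
  four cucumber) are appended verbatim as fixed validation anchors.
* **Step-change light response:** the four published transitions
  (200→200, 50→200, 200→50, 50→50 µmol m⁻² s⁻¹), five intensities per
  curve (50–1200), n = 20 points, Gaussian noise sd 4 µmol e⁻ m⁻² s⁻¹ on
  the rate — the published design's footprint.  Leaf optics come from the
  trait pipeline on the anchor traits.
* **Canopy time series:** a prototype monopodial plant initiating a leaf
  every 2.5 days with logistic leaf-area expansion (asymptote 300 cm²);
  sinusoidal diurnal PPFD (daylight 06–18 h, base midday amplitude
  700 µmol m⁻² s⁻¹) with day-to-day lognormal amplitude variability
  (sd 0.5 — overcast-to-clear contrast; without realistic day-to-day
  variability the averaging depth `d` is unidentifiable); air temperature
  cycling 17–23 °C.  Weekly observations from day 42 on leaves aged 20–57
  days, 46 in total, with additive noise on J_max and V_cmax.

What the generators do **not** emulate: real spectral shapes beyond the
parametric bands, measurement-protocol autocorrelation, within-canopy
temperature gradients, starch dynamics in LMA, and plant-to-plant
variability (one prototype plant).  Passing recovery tests therefore show
the estimation machinery is correct and well-conditioned at the study's
scale and noise — not that the model is validated on real crops.

## Known limitations

* No temperature response of `V_cmax`/`J_max` (everything at 25 °C) and no
  mesophyll-conductance model.
* Point predictions only from the surrogate; its predictive variance is not
  propagated into `J_max`/`V_cmax`.
* Bidirectional (angle-resolved) reflectance, polarization and scattering
  anisotropy are out of scope; the two-stream approximation assumes
  perfectly diffuse streams with symmetric scattering.
* The Monte-Carlo recovery of the step-change acclimation weight `p_i2` at
  the published design scale (20 points, noise sd 4) has a sampling sd of
  about 0.03 — close to the information limit of that design — so
  replicate-level recovery inside a ±10% band cannot be guaranteed at high
  rates; see the recovery tests for the measured distribution.
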