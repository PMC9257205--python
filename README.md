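# photoacclim

Photosynthetic light acclimation from intra-leaf radiation transfer:
predicting the Farquhar–Caemmerer–Berry (FCB) parameters **V<sub>cmax</sub>**
and **J<sub>max</sub>** of individual leaves from their age, pigment/mass
traits and light-interception history.

## Who this is for

Crop and canopy modellers who need vertical, time-resolved profiles of leaf
photosynthetic capacity in monopodial greenhouse crops (tomato, cucumber),
where leaf age and light interception are confounded: leaves are born at the
top of the canopy and sink into shade as they age, so bulk regressions of
capacity on intercepted light cannot separate aging from shading.  This
package separates the two mechanistically, at the intra-leaf level.

## The model

**Radiation transfer.**  Within the mesophyll, downward and upward diffuse
fluxes over cumulative chlorophyll `c` (µg cm⁻²) obey a two-stream system
with scattering and absorption coefficients per unit chlorophyll
(`k_s`, `k_a`, cm² µg⁻¹) and diffuse Fresnel reflectances at the epidermis
(`r_e` external, `r_i` internal, computed from the refractive index by
hemispherical integration).  The closed-form solution maps `(k_s, k_a)` to
bulk reflectance and transmittance `(R, T)` and back.

**Simplified absorbed-light profile.**  Spectral profiles are integrated
under a D55 daylight weighting with photosynthetic effectiveness 1.0 for
chlorophylls and 0.7 for carotenoids, then condensed to a stretched
exponential

    I_a(c, w_u, I0, k) = I0 · p1·k_a · [ w_u e^(−k c^p2) + (1−w_u) e^(−k (Chl−c)^p2) ]

with `p2 = 0.664` fixed (a stretched exponent fits the mixture of spectral
decay rates far better than a plain exponential), `w_u` the upper-side light
fraction, and `p1` allowing the internal flux to exceed the incident one
(internal reflection).  A Gaussian-process surrogate predicts
`(p1·k_a, k, T)` directly from bulk traits (Chl, Car, LMA), replacing the
spectral chain at run time.

**Electron transport.**  The local rate follows a non-rectangular hyperbola
with curvature θ between the light-limited slope `φ·I_a` (φ = 0.468) and a
capacity profile

    J_c,max(c) = min{ J_c,max,mx(t), max[ J_c,max,mn(t), φ·I_a(c, w_u,g, I*, p3·k) ] }

that acclimates to the growth environment through a characteristic intensity
`I*` and a flattened extinction `k′ = p3·k` (p3 = 0.54: capacity profiles
are shallower than light profiles).  Whole-leaf `J_leaf` integrates the rate
over `c`; the retrieved `J_max` is the leaf rate at the (cuvette-corrected)
measurement PPFD, and `V_cmax = p4 · ∫ J_c,max dc`.

**Acclimation and aging.**  `I*` comes either from a step-change model
(`I* = p_i1 (p_i2 I1 + (1−p_i2) I2)`) or from the mean PPFD intercepted over
the previous `d` days through the overlying canopy
(`I0 e^(−0.72·LAI)`, daylight hours only).  An hourly thermal-time clock
(trapezoidal response with tomato cardinal temperatures) accumulates
`PR_sum` from leaf appearance and drives declining ontogenetic limits
`J_c,max,mn = p_J0 − p_J1 √PR_sum`, `J_c,max,mx = 2.6 · J_c,max,mn`.

Calibration workflows are statsmodels-style model objects whose `fit()`
returns a results object with estimates, 95% confidence intervals, RMSE and
a `summary()` table.  Synthetic-data generators emulate every study design
used for calibration, so all fits are validated by parameter recovery.

## Worked example

```python
import photoacclim as pa

# a mid-canopy tomato leaf
traits = pa.LeafTraits(chl=40.0, car=8.0, lma=40.0)

# optics -> stretched-exponential profile parameters
pipe = pa.leaf_profile_pipeline(traits, jitter_sd=0.0)
print(f"p1*ka = {pipe['p1ka']:.4f} cm2/ug, k = {pipe['k']:.4f}, "
      f"T = {pipe['T']:.3f}")

# electron transport for a leaf acclimated to I* = 300 umol m-2 s-1
prof = pipe["params"]
params = pa.ETRParams(jc_max_mn=161.0, jc_max_mx=418.6, i_star=300.0,
                      w_u_g=0.9, w_u_m=0.95)
jmax = pa.operational_jmax(params, prof, traits.chl, T=pipe["T"])
vc = pa.vcmax(params, prof, traits.chl)
print(f"J_max = {jmax:.1f} umol e- m-2 s-1, V_cmax = {vc:.1f} umol m-2 s-1")
```

prints

```
p1*ka = 0.0346 cm2/ug, k = 0.0991, T = 0.156
J_max = 134.1 umol e- m-2 s-1, V_cmax = 59.4 umol m-2 s-1
```

`p1*ka` is the broadband absorbed fraction per unit chlorophyll at the top
of the mesophyll, `k` the effective extinction of the stretched-exponential
profile, `T` the daylight-weighted leaf transmittance (feeding the cuvette
correction), and the last line gives the two FCB parameters at 25 °C for a
leaf whose capacity band spans 161–418.6 mmol e⁻ (mol Chl)⁻¹ s⁻¹.

The same pipeline scales to populations and time series:

```python
from photoacclim import (generate_canopy_timeseries, fit_canopy_acclimation)

obs, histories, truth = generate_canopy_timeseries(seed=1)
res = fit_canopy_acclimation(obs, histories)
print(res.summary())          # p_i1, p4, p_J0, p_J1 with CIs, selected d
```

A command-line interface mirrors the workflow stages
(`photoacclim optics|profile|surrogate|etr|acclim|fit|fixtures --help`).

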