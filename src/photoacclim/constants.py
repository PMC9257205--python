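"""Registry of model constants.

Every empirical constant used by more than one module lives here, with units,
so that a run can echo the full registry and overrides stay explicit.  The
values are the published point estimates for the crops they were estimated on
(cucumber light-response curves, tomato canopy series, spinach/eucalyptus
capacity profiles); all are configurable at call sites.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


#: Exponent of the stretched-exponential light profile, fitted once over a
#: large leaf population and then held fixed (dimensionless).
P2_DEFAULT = 0.664

#: Capacity-profile scaling: the extinction coefficient of the electron
#: transport capacity profile is p3 * k (dimensionless).
P3_DEFAULT = 0.54

#: Curvature of the non-rectangular hyperbola for electron transport
#: (dimensionless, cucumber estimate).
THETA_DEFAULT = 0.962

#: PSII quantum efficiency of electron transport for absorbed photons,
#: mol e- per mol photons; from f_cyc = 0 and Phi_2m = 0.88.
PHI_DEFAULT = 0.468

#: Maximum electron transport efficiency of PSII (dimensionless).
PHI2M_DEFAULT = 0.88

#: Gas-exchange chamber lower-wall reflectance (LI-6400-type cuvette).
R_CH_DEFAULT = 0.5

#: Crop diffuse extinction coefficient for canopy light interception.
K_CANOPY_DEFAULT = 0.72

#: CO2 compensation point without day respiration, ppm, 25 degC.
GAMMA_STAR_DEFAULT = 42.75

#: Chl-enhancement coefficient for light received during leaf expansion,
#: ug cm-2 per (mol m-2) of PPFD anomaly.
M_CHL_DEFAULT = 0.0447

#: Ratio of maximum to minimum electron transport capacity per unit Chl.
N_RATIO_DEFAULT = 2.6

#: Ground area per plant in the tomato canopy, cm2.
S_P_DEFAULT = 4167.0

#: Molar mass used to convert chlorophyll a+b mass to moles, g mol-1.
CHL_MOLAR_MASS_DEFAULT = 900.0

#: Measurement PPFD of the gas-exchange protocol, umol m-2 s-1.
I0_MEASUREMENT_DEFAULT = 1500.0

#: Number of previous days over which intercepted PPFD is averaged.
D_DAYS_DEFAULT = 3

#: Proportionality V_cmax = p4 * integral of capacity (tomato estimate).
P4_DEFAULT = 0.437

#: Empirical acclimation-intensity coefficients: step-change (cucumber).
PI1_STEP_DEFAULT = 1.51
PI2_STEP_DEFAULT = 0.446

#: Empirical acclimation-intensity coefficient: history mean (tomato).
PI1_HISTORY_DEFAULT = 0.586

#: Aging parameters of the lower capacity limit, mmol e- (mol Chl)-1 s-1
#: and the same per sqrt(hour) of accumulated phenological response.
PJ0_DEFAULT = 304.0
PJ1_DEFAULT = 7.0

#: Lower capacity limit estimated for light-acclimated cucumber leaves,
#: mmol e- (mol Chl)-1 s-1.
JCMAX_MN_CUCUMBER = 161.0

#: Chl calibration from four-band remission readings (slope, intercept).
CHL_REMISSION_SLOPE = 57.74
CHL_REMISSION_INTERCEPT = -18.11

#: Single-leaf area from length and width: S_L = A*W*L + B (cm2).
LEAF_AREA_SLOPE = 0.2568
LEAF_AREA_INTERCEPT = 11.725

#: Trapezoidal phenology-response cardinal temperatures, degC
#: (tomato-typical; base, lower optimum, upper optimum, maximum).
CARDINALS_DEFAULT = (10.0, 28.0, 32.0, 48.0)

#: Photosynthetic effectiveness of absorbed quanta by pigment class.
EFFECTIVENESS_DEFAULT = {"chl": 1.0, "car": 0.7, "other": 0.0}


@dataclass
class RunConfig:
    """Bundle of run-level settings echoed by the CLI and fit logs."""

    seed: int = 0
    wavelength_min: float = 400.0
    wavelength_max: float = 700.0
    wavelength_step: float = 5.0
    p2: float = P2_DEFAULT
    p3: float = P3_DEFAULT
    theta: float = THETA_DEFAULT
    phi: float = PHI_DEFAULT
    r_ch: float = R_CH_DEFAULT
    k_canopy: float = K_CANOPY_DEFAULT
    gamma_star: float = GAMMA_STAR_DEFAULT
    m_chl: float = M_CHL_DEFAULT
    n_ratio: float = N_RATIO_DEFAULT
    s_p: float = S_P_DEFAULT
    chl_molar_mass: float = CHL_MOLAR_MASS_DEFAULT
    overrides: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)

    def override(self, **kwargs) -> "RunConfig":
        """Return a copy with explicit overrides recorded."""
        d = self.as_dict()
        rec = dict(d.pop("overrides"))
        for key, value in kwargs.items():
            if key not in d:
                raise KeyError(f"unknown config key: {key!r}")
            rec[key] = value
            d[key] = value
        return RunConfig(**d, overrides=rec)
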