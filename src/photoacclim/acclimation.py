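"""Light-history and aging drivers of photosynthetic capacity.

Two empirical models set the characteristic acclimation intensity ``I*``:
a step-change form combining the intensities before and after a transfer
(``I* = p_i1 (p_i2 I1 + (1 - p_i2) I2)``) and a history form proportional
to the mean PPFD intercepted over the last ``d`` days
(``I* = p_i1 * mean PPFD``).  Interception attenuates the above-canopy flux
through the overlying leaf area, ``I0 exp(-k LAI_t)``, averaged over
daylight hours.

Leaf aging is tracked by the hourly sum of a trapezoidal phenology
(thermal-time) response since leaf appearance, ``PR_sum``; it drives the
ontogenetic capacity limits ``J_c,max,mn = p_J0 +/- p_J1 sqrt(PR_sum)``
(sign configurable; the default is a decline with age) and
``J_c,max,mx = n * J_c,max,mn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants
from .exceptions import InvalidInputError
from .profile import LeafTraits, ProfileParams, absorbed_light, leaf_profile_pipeline

__all__ = [
    "LightHistory",
    "PhenologyState",
    "AgingParams",
    "phenology_response",
    "mean_intercepted_ppfd",
    "istar_step",
    "istar_history",
    "aging_limits",
    "simulate_timecourse",
]


@dataclass
class LightHistory:
    """Hourly above-canopy PPFD, overlying LAI and air temperature."""

    data: pd.DataFrame  # columns: timestamp, i0_ppfd, lai_above, t_air_c

    def __post_init__(self):
        df = self.data.copy()
        required = {"timestamp", "i0_ppfd", "lai_above", "t_air_c"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(f"history missing columns: {sorted(missing)}")
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        dt = df["timestamp"].diff().dropna()
        if len(df) > 1 and not (dt == pd.Timedelta(hours=1)).all():
            raise InvalidInputError("history must be strictly hourly")
        if (df["i0_ppfd"] < 0).any() or (df["lai_above"] < 0).any():
            raise InvalidInputError("fluxes and LAI must be nonnegative")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class PhenologyState:
    """Cardinal temperatures and the accumulated phenology response."""

    cardinals: tuple[float, float, float, float] = constants.CARDINALS_DEFAULT
    pr_sum: float = 0.0

    def __post_init__(self):
        base, lo, hi, tmax = self.cardinals
        if not (base < lo <= hi < tmax):
            raise InvalidInputError(
                "cardinals must satisfy base < opt_low <= opt_high < max"
            )
        if self.pr_sum < 0:
            raise InvalidInputError("PR_sum must be nonnegative")

    def advance(self, t_air_hours) -> "PhenologyState":
        """Accumulate hourly responses; returns a new state."""
        r = phenology_response(np.asarray(t_air_hours, float), self.cardinals)
        return PhenologyState(self.cardinals, self.pr_sum + float(np.sum(r)))


@dataclass(frozen=True)
class AgingParams:
    """Ontogenetic capacity-limit parameters.

    pj0      : mmol e- (mol Chl)-1 s-1, capacity floor at leaf appearance
    pj1      : same units per sqrt(hour) of accumulated phenology response
    n_ratio  : upper/lower limit ratio (>= 1)
    age_sign : -1 for a decline of the lower limit with age (default,
               matching the observed monotone decline), +1 for an increase
    """

    pj0: float = constants.PJ0_DEFAULT
    pj1: float = constants.PJ1_DEFAULT
    n_ratio: float = constants.N_RATIO_DEFAULT
    age_sign: int = -1

    def __post_init__(self):
        if self.pj0 <= 0:
            raise InvalidInputError("pj0 must be positive")
        if self.n_ratio < 1:
            raise InvalidInputError("n_ratio must be >= 1")
        if self.age_sign not in (-1, 1):
            raise InvalidInputError("age_sign must be +1 or -1")


def phenology_response(t_air, cardinals=constants.CARDINALS_DEFAULT):
    """Trapezoidal thermal-time response in [0, 1].

    Zero at/below the base and at/above the maximum temperature, one on the
    optimum plateau, linear ramps between.
    """
    base, lo, hi, tmax = cardinals
    if not (base < lo <= hi < tmax):
        raise InvalidInputError("invalid cardinal temperatures")
    t = np.asarray(t_air, dtype=float)
    up = (t - base) / (lo - base)
    down = (tmax - t) / (tmax - hi)
    r = np.clip(np.minimum(up, down), 0.0, 1.0)
    return float(r) if np.isscalar(t_air) else r


def mean_intercepted_ppfd(
    history: LightHistory,
    k_canopy: float = constants.K_CANOPY_DEFAULT,
    d: int = constants.D_DAYS_DEFAULT,
    reference_time=None,
    daylight_threshold: float = 1.0,
    decay: float | None = None,
) -> float:
    """Mean PPFD intercepted by the leaf over the previous ``d`` days.

    Hourly above-canopy PPFD attenuated through the overlying leaf area,
    ``i0 exp(-k_canopy lai_above)``, averaged over the daylight hours
    (``i0 > daylight_threshold``) of the ``d`` whole days ending at the end
    of the day before ``reference_time`` (default: the day after the last
    record, i.e. the full trailing window).  ``decay`` switches to
    exponentially decaying day weights ``exp(-age/decay)`` instead of equal
    weighting.
    """
    if d < 1 or int(d) != d:
        raise InvalidInputError("d must be a positive integer number of days")
    df = history.data
    if reference_time is None:
        end = df["timestamp"].iloc[-1].normalize() + pd.Timedelta(days=1)
    else:
        end = pd.to_datetime(reference_time).normalize()
    start = end - pd.Timedelta(days=int(d))
    window = df[(df["timestamp"] >= start) & (df["timestamp"] < end)]
    span_hours = int(d) * 24
    if len(window) < span_hours:
        raise InvalidInputError(
            f"history must cover {span_hours} hourly records in "
            f"[{start}, {end}); found {len(window)}"
        )
    day = window[window["i0_ppfd"] > daylight_threshold]
    if day.empty:
        raise InvalidInputError("no daylight hours in the averaging window")
    intercepted = day["i0_ppfd"].to_numpy() * np.exp(
        -k_canopy * day["lai_above"].to_numpy()
    )
    if decay is None:
        return float(intercepted.mean())
    age_days = (end - day["timestamp"]).dt.total_seconds().to_numpy() / 86400.0
    w = np.exp(-age_days / decay)
    return float(np.sum(w * intercepted) / np.sum(w))


def istar_step(i1: float, i2: float, p_i1: float, p_i2: float) -> float:
    """Acclimation intensity after a step change in growth irradiance:
    ``I* = p_i1 (p_i2 I1 + (1 - p_i2) I2)``."""
    if i1 < 0 or i2 < 0:
        raise InvalidInputError("intensities must be nonnegative")
    return p_i1 * (p_i2 * i1 + (1.0 - p_i2) * i2)


def istar_history(ppfd_bar: float, p_i1: float) -> float:
    """Acclimation intensity from intercepted-light history:
    ``I* = p_i1 * mean PPFD``."""
    if ppfd_bar < 0:
        raise InvalidInputError("ppfd_bar must be nonnegative")
    return p_i1 * ppfd_bar


def aging_limits(pr_sum, params: AgingParams) -> tuple:
    """Ontogenetic capacity limits from accumulated phenology response.

    ``J_c,max,mn = max(0, pj0 + age_sign * pj1 * sqrt(PR_sum))`` and
    ``J_c,max,mx = n_ratio * J_c,max,mn``.
    """
    pr = np.asarray(pr_sum, dtype=float)
    if np.any(pr < 0):
        raise InvalidInputError("PR_sum must be nonnegative")
    mn = np.maximum(params.pj0 + params.age_sign * params.pj1 * np.sqrt(pr), 0.0)
    mx = params.n_ratio * mn
    if np.isscalar(pr_sum):
        return float(mn), float(mx)
    return mn, mx


def simulate_timecourse(
    i0: float,
    traits: LeafTraits,
    horizon_days: int,
    t_air: float = 23.0,
    p_i1: float = constants.PI1_HISTORY_DEFAULT,
    aging: AgingParams | None = None,
    profile: ProfileParams | None = None,
    leaf_T: float | None = None,
    phi: float = constants.PHI_DEFAULT,
    theta: float = constants.THETA_DEFAULT,
    p3: float = constants.P3_DEFAULT,
    p4: float = constants.P4_DEFAULT,
    w_u_g: float = 0.7,
    cardinals=constants.CARDINALS_DEFAULT,
    chl_molar_mass: float = constants.CHL_MOLAR_MASS_DEFAULT,
) -> pd.DataFrame:
    """Daily time course of capacity limits, leaf rate and V_cmax at
    constant PPFD and temperature.

    The leaf keeps constant traits; its optical parameters come from the
    trait pipeline unless ``profile`` (and broadband transmittance
    ``leaf_T``) are supplied.  Light acclimation is at steady state
    (``I* = p_i1 i0``) while the ontogenetic limits move with the phenology
    clock.  Per day the output reports the limits, the unclamped light-set
    capacity range, the realized mean leaf rate per unit chlorophyll at the
    growth light, and V_cmax.
    """
    # local import: calibration-free forward machinery only
    from .etr import ETRParams, capacity_profile, integrate_jleaf, vcmax as _vcmax

    if horizon_days < 0:
        raise InvalidInputError("horizon_days must be >= 0")
    aging = aging or AgingParams()
    if profile is None:
        pipe = leaf_profile_pipeline(traits, jitter_sd=0.0)
        profile = pipe["params"]
    i_star = istar_history(i0, p_i1)
    resp = phenology_response(t_air, cardinals)
    conv = chl_molar_mass / 10.0
    chl = traits.chl
    mol_chl = chl * 0.01 / chl_molar_mass  # mol Chl per m2

    rows = []
    for day in range(1, horizon_days + 1):
        pr_sum = 24.0 * resp * day
        jmn, jmx = aging_limits(pr_sum, aging)
        params = ETRParams(
            phi=phi, theta=theta, p3=p3, jc_max_mn=jmn, jc_max_mx=jmx,
            i_star=i_star, w_u_g=w_u_g, w_u_m=w_u_g, p4=p4,
            chl_molar_mass=chl_molar_mass,
        )
        mod = profile.with_k(p3 * profile.k)
        cs = np.linspace(0.0, chl, 201)
        light_set = phi * conv * absorbed_light(cs, w_u_g, i_star, mod, chl)
        j_leaf = integrate_jleaf(i0, chl, params, profile)
        rows.append(
            {
                "day": day,
                "pr_sum": pr_sum,
                "jc_max_mn": jmn,
                "jc_max_mx": jmx,
                "cap_light_min": float(light_set.min()),
                "cap_light_max": float(light_set.max()),
                "j_leaf": j_leaf,
                "mean_rate": j_leaf / mol_chl / 1000.0,  # mmol e-/mol Chl/s
                "vcmax": _vcmax(params, profile, chl),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "day", "pr_sum", "jc_max_mn", "jc_max_mx", "cap_light_min",
            "cap_light_max", "j_leaf", "mean_rate", "vcmax",
        ],
    )
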