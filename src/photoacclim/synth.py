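"""Synthetic datasets emulating the study designs the model is fitted to.

Three generators:

* a leaf population with realistic covariation of chlorophyll, carotenoid
  and leaf-mass-per-area (log-normal marginals, positive Chl-LMA
  correlation) for training the trait surrogate;
* electron-transport light-response curves measured seven days after a step
  change in growth irradiance (four transitions, cuvette geometry);
* a vertically grown greenhouse canopy followed over weeks: hourly PPFD and
  temperature, sequential leaf appearance, leaf-area growth, vertical
  chlorophyll/LMA profiles, and weekly noisy J_max/V_cmax retrievals.

Every generator is deterministic given its seed and records the generating
truth so parameter-recovery studies can compare against it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import constants
from .acclimation import AgingParams, LightHistory, aging_limits, phenology_response
from .calibration import CanopyAcclimationModel, LightResponseModel
from .canopy import chl_profile_adjust, lma_profile
from .exceptions import InvalidInputError
from .profile import LeafTraits, leaf_profile_pipeline

__all__ = [
    "TABLE1_ANCHORS",
    "generate_leaf_population",
    "generate_light_response_dataset",
    "generate_canopy_timeseries",
]

#: Measured leaf properties of the species used for model testing
#: (validation anchors appended verbatim to generated populations).
TABLE1_ANCHORS = pd.DataFrame(
    [
        # species, growth PPFD label, chl ug/cm2, lma g/m2, chl2car, w_u_g
        ("spinach_sun", "800", 56.3, 48.0, 4.46, 0.9),
        ("spinach_shade", "200", 48.8, 37.0, 4.84, 0.9),
        ("eucalyptus", "natural", 44.8, 240.0, 4.25, 0.5),
        ("cucumber_ml_ml", "200->200", 57.0, 27.6, 5.3, 0.9),
        ("cucumber_ll_ml", "50->200", 54.9, 24.3, 5.4, 0.9),
        ("cucumber_ml_ll", "200->50", 56.3, 23.3, 5.4, 0.9),
        ("cucumber_ll_ll", "50->50", 40.0, 15.4, 5.5, 0.9),
    ],
    columns=["source", "growth_ppfd", "chl", "lma", "chl2car", "w_u_g"],
)


def generate_leaf_population(
    n: int, seed: int = 0, include_anchors: bool = True
) -> pd.DataFrame:
    """Sample a leaf-trait population for surrogate training.

    Log-normal Chl and LMA with a positive rank correlation (Gaussian
    copula, rho = 0.5), Chl within [15, 80] ug/cm2, LMA within
    [15, 250] g/m2, chlorophyll-to-carotenoid ratio uniform in [4, 6], and
    a leaf water column (g/m2) loosely proportional to LMA (used only by
    the lower-percentile quality filter).  Known measured leaves are
    appended as fixed validation anchors.
    """
    if n < 30:
        raise InvalidInputError("population size must be >= 30")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = 0.5 * z1 + np.sqrt(1 - 0.5**2) * rng.standard_normal(n)
    chl = np.clip(np.exp(np.log(42.0) + 0.32 * z1), 15.0, 80.0)
    lma = np.clip(np.exp(np.log(45.0) + 0.55 * z2), 15.0, 250.0)
    ratio = rng.uniform(4.0, 6.0, n)
    water = lma * rng.uniform(1.5, 2.5, n)
    pop = pd.DataFrame(
        {
            "chl": chl,
            "car": chl / ratio,
            "lma": lma,
            "chl2car": ratio,
            "water": water,
            "source": "synthetic",
        }
    )
    if include_anchors:
        anchors = TABLE1_ANCHORS.assign(
            car=lambda df: df["chl"] / df["chl2car"],
            water=lambda df: df["lma"] * 2.0,
        )[["chl", "car", "lma", "chl2car", "water", "source"]]
        pop = pd.concat([pop, anchors], ignore_index=True)
    return pop


# ---------------------------------------------------------------------------
# step-change light-response experiment
# ---------------------------------------------------------------------------

_DEFAULT_TREATMENTS = ((200.0, 200.0), (50.0, 200.0), (200.0, 50.0),
                       (50.0, 50.0))
_TREATMENT_SOURCES = {
    (200.0, 200.0): "cucumber_ml_ml",
    (50.0, 200.0): "cucumber_ll_ml",
    (200.0, 50.0): "cucumber_ml_ll",
    (50.0, 50.0): "cucumber_ll_ll",
}
_DEFAULT_INTENSITIES = (50.0, 100.0, 250.0, 600.0, 1200.0)

_LR_TRUTH_DEFAULT = {
    "p_i1": constants.PI1_STEP_DEFAULT,
    "p_i2": constants.PI2_STEP_DEFAULT,
    "theta": constants.THETA_DEFAULT,
    "jc_max_mn": constants.JCMAX_MN_CUCUMBER,
}


def treatment_leaf_params(
    treatments=_DEFAULT_TREATMENTS, seed: int = 0
) -> pd.DataFrame:
    """Optical parameters of the measured leaf in each treatment, computed
    once through the full trait pipeline (deterministic)."""
    rows = {}
    for tr in treatments:
        key = (float(tr[0]), float(tr[1]))
        src = _TREATMENT_SOURCES.get(key)
        if src is None:
            raise InvalidInputError(f"no anchor leaf for treatment {tr}")
        anchor = TABLE1_ANCHORS.set_index("source").loc[src]
        traits = LeafTraits.from_chl2car(
            anchor["chl"], anchor["chl2car"], anchor["lma"]
        )
        out = leaf_profile_pipeline(traits, seed=seed, jitter_sd=0.0)
        rows[f"{key[0]:g}->{key[1]:g}"] = {
            "chl": traits.chl, "car": traits.car, "lma": traits.lma,
            "p1ka": out["p1ka"], "k": out["k"], "T": out["T"],
        }
    return pd.DataFrame(rows).T


def generate_light_response_dataset(
    true_params: dict | None = None,
    treatments=_DEFAULT_TREATMENTS,
    intensities=_DEFAULT_INTENSITIES,
    noise_sd: float = 4.0,
    seed: int = 0,
    leaf_params: pd.DataFrame | None = None,
    fixed: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Forward-simulate a step-change light-response experiment.

    Returns ``(data, leaf_params, truth)`` where ``data`` has one row per
    measured point (columns ``treatment, i1, i2, i0, jleaf`` with Gaussian
    noise of ``noise_sd`` umol e- m-2 s-1 on the rate) and ``truth`` the
    generating parameters.  ``leaf_params`` may be supplied to skip the
    optics pipeline (it is deterministic for the default treatments).
    """
    if len(treatments) < 1:
        raise InvalidInputError("need at least one treatment")
    truth = dict(_LR_TRUTH_DEFAULT)
    truth.update(true_params or {})
    if leaf_params is None:
        leaf_params = treatment_leaf_params(treatments, seed=0)
    rows = []
    for i1, i2 in treatments:
        label = f"{i1:g}->{i2:g}"
        for i0 in intensities:
            rows.append({"treatment": label, "i1": i1, "i2": i2,
                         "i0": float(i0), "jleaf": 0.0})
    data = pd.DataFrame(rows)
    skeleton = LightResponseModel(data, leaf_params, fixed=fixed)
    clean = skeleton.predict(
        truth["p_i1"], truth["p_i2"], truth["theta"], truth["jc_max_mn"]
    )
    rng = np.random.default_rng(seed)
    data["jleaf"] = clean + noise_sd * rng.standard_normal(len(data))
    truth["noise_sd"] = noise_sd
    truth["jleaf_clean"] = clean
    return data, leaf_params, truth


# ---------------------------------------------------------------------------
# greenhouse canopy time series
# ---------------------------------------------------------------------------

_CANOPY_TRUTH_DEFAULT = {
    "p_i1": constants.PI1_HISTORY_DEFAULT,
    "p4": constants.P4_DEFAULT,
    "p_j0": constants.PJ0_DEFAULT,
    "p_j1": constants.PJ1_DEFAULT,
    "d": constants.D_DAYS_DEFAULT,
    "age_sign": -1,
}


def _hourly_weather(days: int, rng, base_amplitude: float = 700.0,
                    amp_sd: float = 0.5, start="2018-03-01"):
    """Sinusoidal diurnal PPFD (daylight 6-18 h) with day-to-day lognormal
    amplitude noise, and a day/night air-temperature cycle."""
    hours = pd.date_range(start, periods=days * 24, freq="h")
    h = hours.hour.to_numpy()
    day_idx = np.arange(days).repeat(24)
    amp = base_amplitude * np.exp(amp_sd * rng.standard_normal(days))
    shape = np.sin(np.pi * np.clip((h - 6) / 12.0, 0.0, 1.0))
    shape[(h < 6) | (h >= 18)] = 0.0
    ppfd = amp[day_idx] * shape
    t_air = 17.0 + 6.0 * shape  # 23 degC midday, 17 degC night
    return hours, ppfd, t_air


def _leaf_area_curve(age_days, s_max: float = 300.0):
    """Logistic single-leaf area expansion (cm2) over ~3 weeks."""
    a = np.asarray(age_days, dtype=float)
    return np.where(a <= 0, 0.0, s_max / (1.0 + np.exp(-(a - 10.0) / 4.0)))


def generate_canopy_timeseries(
    true_params: dict | None = None,
    days: int = 70,
    n_obs: int = 46,
    phyllochron_days: float = 2.5,
    seed: int = 0,
    jmax_noise_sd: float = 4.0,
    vcmax_noise_sd: float = 2.0,
    s_p: float = constants.S_P_DEFAULT,
    fixed: dict | None = None,
) -> tuple[pd.DataFrame, dict, dict]:
    """Forward-simulate a monopodial greenhouse canopy experiment.

    A prototype plant initiates one leaf every ``phyllochron_days``; leaves
    expand logistically, so younger (upper) leaves shade older ones less
    than mature ones would.  Hourly above-canopy PPFD/temperature drive each
    leaf's intercepted light and phenology clock.  Weekly from day 42,
    leaves aged 20-57 days are "measured": their J_max and V_cmax are
    forward-simulated from the generating truth (acclimation intensity from
    the previous ``d`` days, aging limits from accumulated phenology
    response) and observation noise is added.

    Returns ``(obs, histories, truth)`` ready for
    :class:`~photoacclim.calibration.CanopyAcclimationModel`.
    """
    truth = dict(_CANOPY_TRUTH_DEFAULT)
    truth.update(true_params or {})
    d_true = int(truth["d"])
    if days < 2 * max(d_true, constants.D_DAYS_DEFAULT) + 14:
        raise InvalidInputError("simulation horizon too short")
    rng = np.random.default_rng(seed)
    hours, ppfd, t_air = _hourly_weather(days, rng)
    n_hours = len(hours)
    hour_of_sim = np.arange(n_hours) / 24.0  # days since start

    n_leaves = int(days / phyllochron_days)
    appear = np.arange(n_leaves) * phyllochron_days  # leaf 0 = oldest/bottom
    # leaf areas over time: (n_leaves, n_hours)
    age = hour_of_sim[None, :] - appear[:, None]
    areas = _leaf_area_curve(age)
    # overlying LAI per leaf: leaves with larger index sit above
    above = np.cumsum(areas[::-1], axis=0)[::-1] - areas  # sum of areas above
    lai_above = (2.0 * above + areas) / s_p

    resp = phenology_response(t_air)
    obs_days = list(range(42, days + 1, 7))
    aging = AgingParams(pj0=truth["p_j0"], pj1=truth["p_j1"],
                        age_sign=int(truth["age_sign"]))

    # expansion-phase intercepted PPFD (mol m-2 over 21 days) for the Chl
    # adjustment, per leaf
    exp_ppfd = np.zeros(n_leaves)
    for j in range(n_leaves):
        mask = (age[j] > 0) & (age[j] <= 21)
        exp_ppfd[j] = np.sum(
            ppfd[mask] * np.exp(-constants.K_CANOPY_DEFAULT * lai_above[j][mask])
        ) * 3600e-6
    exp_mean = float(exp_ppfd[exp_ppfd > 0].mean())

    pipe_cache: dict[tuple, dict] = {}
    rows, histories = [], {}
    for od in obs_days:
        t_idx = min(od * 24, n_hours) - 1
        present = np.flatnonzero((appear < od) & (areas[:, t_idx] > 20.0))
        ages_at_obs = od - appear[present]
        eligible = present[(ages_at_obs >= 20) & (ages_at_obs <= 57)]
        if eligible.size == 0:
            continue
        take = max(1, int(np.ceil(n_obs / len(obs_days))))
        chosen = rng.choice(eligible, size=min(take, eligible.size),
                            replace=False)
        n_present = present.size
        for j in sorted(chosen):
            rank = np.searchsorted(present, j)
            z = rank / max(n_present - 1, 1)
            chl_mean = 32.0 + 18.0 * z
            chl = chl_profile_adjust(z, chl_mean, exp_ppfd[j], exp_mean)
            chl = float(np.clip(chl, 15.0, 80.0))
            lma = float(lma_profile(z, lma_bottom=28.0, gain=0.8))
            key = (round(chl, 1), round(lma, 1))
            if key not in pipe_cache:
                traits = LeafTraits(chl=key[0], car=key[0] / 5.2, lma=key[1])
                pipe_cache[key] = leaf_profile_pipeline(traits, jitter_sd=0.0)
            pipe = pipe_cache[key]
            appear_idx = int(appear[j] * 24)
            pr_sum = float(np.sum(resp[appear_idx:od * 24]))
            leaf_id = f"leaf{j:02d}"
            if leaf_id not in histories:
                histories[leaf_id] = LightHistory(pd.DataFrame(
                    {"timestamp": hours, "i0_ppfd": ppfd,
                     "lai_above": lai_above[j], "t_air_c": t_air}
                ))
            rows.append({
                "leaf_id": leaf_id,
                "date": hours[0] + pd.Timedelta(days=od),
                "day": od, "layer": int(8 * (1 - z)) + 1, "z_rel": z,
                "age_days": float(od - appear[j]),
                "chl": key[0], "car": key[0] / 5.2, "lma": key[1],
                "p1ka": pipe["p1ka"], "k": pipe["k"], "T": pipe["T"],
                "pr_sum": pr_sum, "jmax_obs": 0.0, "vcmax_obs": 0.0,
            })
    obs = pd.DataFrame(rows)
    if len(obs) > n_obs:
        obs = obs.sample(n=n_obs, random_state=seed).sort_index().reset_index(
            drop=True)
    skeleton = CanopyAcclimationModel(obs, histories, fixed=fixed)
    jmax_clean, vcmax_clean = skeleton.predict(
        truth["p_i1"], truth["p4"], truth["p_j0"], truth["p_j1"], d=d_true
    )
    obs["jmax_obs"] = jmax_clean + jmax_noise_sd * rng.standard_normal(len(obs))
    obs["vcmax_obs"] = vcmax_clean + vcmax_noise_sd * rng.standard_normal(
        len(obs))
    truth.update({
        "jmax_clean": jmax_clean, "vcmax_clean": vcmax_clean,
        "jmax_noise_sd": jmax_noise_sd, "vcmax_noise_sd": vcmax_noise_sd,
        "jc_limits_at_obs": aging_limits(obs["pr_sum"].to_numpy(), aging),
    })
    return obs, histories, truth
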