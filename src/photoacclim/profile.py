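"""Simplified absorbed-light profiles within the mesophyll.

The per-wavelength two-stream solutions are collapsed to a broadband
photosynthetically-weighted profile of incident light over cumulative
chlorophyll, which is then approximated by a stretched exponential::

    I_a(c) = k_a I(c) = I_0 p1 k_a exp(-k c**p2)

with scaling ``p1`` (internal flux at the top mesophyll may exceed the
incident flux because of internal reflection, so ``p1`` can exceed 1),
effective extinction ``k`` (units depend on ``p2``: per (ug cm-2)**p2) and
exponent ``p2``.  A stretched exponent ``p2 < 1`` captures the mixture of
per-wavelength decay rates far better than a plain exponential.  For
two-sided illumination with fraction ``w_u`` incident on the upper side::

    I_a(c, w_u, I_0, k) = I_0 p1 k_a (w_u exp(-k c**p2)
                          + (1 - w_u) exp(-k (Chl - c)**p2))

The same functional form, with extinction rescaled by a factor ``p3``,
describes the normalized profile of photosynthetic capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from . import constants
from .exceptions import ConvergenceError, GridMismatchError, InvalidInputError
from .illuminant import Illuminant
from .optics import (
    RadiationProfile,
    SpectralGrid,
    TwoStreamCoefficients,
    TwoStreamSolution,
    diffuse_interface_reflectance,
    invert_RT,
    leaf_optical_depths,
    synth_leaf_spectrum,
)

__all__ = [
    "LeafTraits",
    "ProfileParams",
    "broadband_profile",
    "fit_profile_params",
    "absorbed_light",
    "normalized_capacity_curve",
    "leaf_profile_pipeline",
]


@dataclass(frozen=True)
class LeafTraits:
    """Bulk per-area leaf properties driving the optical parameterization.

    chl, car : ug cm-2 (chlorophyll a+b; total carotenoids)
    lma      : g m-2 (leaf mass per area, starch-free)
    """

    chl: float
    car: float
    lma: float
    chl2car: float | None = None

    def __post_init__(self):
        if min(self.chl, self.car, self.lma) <= 0:
            raise InvalidInputError("leaf traits must be positive")
        if self.chl2car is not None:
            implied = self.chl / self.car
            if abs(self.chl2car - implied) > 0.01 * implied:
                raise InvalidInputError(
                    f"chl2car={self.chl2car:g} inconsistent with "
                    f"chl/car={implied:g} (tolerance 1%)"
                )

    @classmethod
    def from_chl2car(cls, chl: float, chl2car: float, lma: float) -> "LeafTraits":
        return cls(chl=chl, car=chl / chl2car, lma=lma, chl2car=chl2car)

    @property
    def ratio(self) -> float:
        return self.chl2car if self.chl2car is not None else self.chl / self.car


@dataclass(frozen=True)
class ProfileParams:
    """Parameters of the stretched-exponential absorbed-light profile.

    p1 : dimensionless scaling (may exceed 1)
    p2 : dimensionless stretch exponent, in (0, 2]
    k  : effective extinction, per (ug cm-2)**p2
    ka : broadband effective absorption, cm2 ug-1 (may be None when only
         the profile shape is known; the product p1*ka is what enters the
         absorbed-light computation)
    """

    p1: float
    p2: float
    k: float
    ka: float | None = None

    def __post_init__(self):
        if self.p1 <= 0 or self.k <= 0:
            raise InvalidInputError("p1 and k must be positive")
        if not 0 < self.p2 <= 2:
            raise InvalidInputError("p2 must lie in (0, 2]")
        if self.ka is not None and self.ka <= 0:
            raise InvalidInputError("ka must be positive when given")

    @property
    def p1ka(self) -> float:
        if self.ka is None:
            raise InvalidInputError("ka not set; cannot form p1*ka")
        return self.p1 * self.ka

    @classmethod
    def from_p1ka(cls, p1ka: float, k: float, p2: float = constants.P2_DEFAULT
                  ) -> "ProfileParams":
        """Build from the identifiable product ``p1*ka`` (stored as p1=1)."""
        return cls(p1=1.0, p2=p2, k=k, ka=p1ka)

    def with_k(self, k: float) -> "ProfileParams":
        return replace(self, k=k)


def broadband_profile(
    profile: RadiationProfile,
    coeffs: TwoStreamCoefficients,
    illuminant: Illuminant,
    absorption_fractions: dict | None = None,
    effectiveness: dict | None = None,
    ka_weighting: str = "flux",
) -> tuple[np.ndarray, float]:
    """Collapse per-wavelength profiles to broadband ``I(c)`` and ``k_a``.

    ``profile.I_d/I_u`` must have shape ``(n_c, n_lambda)`` aligned with the
    illuminant grid.  ``I(c) = sum_l w(l) (I_d + I_u)(c, l)``.  The
    broadband absorption coefficient is the flux-weighted mean of
    ``k_a(l)``, with each wavelength's absorption partitioned across pigment
    classes (``absorption_fractions`` maps 'chl'/'car'/'other' to per-l
    fractions summing to 1) and scaled by the photosynthetic effectiveness
    of each class (default: chlorophylls 1.0, carotenoids 0.7, other 0.0).
    With ``ka_weighting='profile'`` the weights are additionally multiplied
    by the depth-averaged total flux at each wavelength.
    """
    eff = dict(constants.EFFECTIVENESS_DEFAULT)
    if effectiveness:
        eff.update(effectiveness)
    total = np.atleast_2d(profile.total.T).T  # (n_c, n_lambda)
    w = illuminant.weights
    ka = np.atleast_1d(np.asarray(coeffs.k_a, dtype=float))
    if total.shape[1] != w.size or ka.size != w.size:
        raise GridMismatchError(
            f"profiles ({total.shape[1]}), coefficients ({ka.size}) and "
            f"illuminant ({w.size}) must share one wavelength grid"
        )
    I_c = total @ w

    if absorption_fractions is None:
        eff_lambda = np.ones_like(ka)
    else:
        eff_lambda = np.zeros_like(ka)
        for key, frac in absorption_fractions.items():
            eff_lambda = eff_lambda + eff.get(key, 0.0) * np.asarray(frac)
    if ka_weighting == "flux":
        wk = w
    elif ka_weighting == "profile":
        wk = w * total.mean(axis=0)
    else:
        raise InvalidInputError(f"unknown ka_weighting: {ka_weighting!r}")
    ka_eff = float(np.sum(wk * ka * eff_lambda) / np.sum(wk))
    return I_c, ka_eff


def fit_profile_params(
    I_c: np.ndarray,
    c: np.ndarray,
    chl: float,
    fix_p2: float | None = None,
    i0: float = 1.0,
    ka: float | None = None,
) -> tuple[ProfileParams, float]:
    """Fit ``I(c) = I0 p1 exp(-k c**p2)`` to a broadband incident profile.

    Unweighted least squares on the profile scale.  With ``fix_p2`` only
    ``(p1, k)`` are free.  Returns the fitted parameters (the broadband
    ``ka``, if supplied, is attached but not fitted — the absorbed profile
    is the incident profile times ``ka``) and the fit RMSE.
    """
    I_c = np.asarray(I_c, dtype=float)
    c = np.asarray(c, dtype=float)
    if I_c.size != c.size or I_c.size < 10:
        raise InvalidInputError("need >= 10 aligned (c, I) points")
    if np.any(I_c <= 0):
        raise InvalidInputError("profile values must be positive")
    y = I_c / i0

    # log-linear initialization at the default stretch exponent
    p2_0 = fix_p2 if fix_p2 is not None else constants.P2_DEFAULT
    cg = np.maximum(c, 1e-9) ** p2_0
    slope, intercept = np.polyfit(cg, np.log(y), 1)
    k0 = max(-slope, 1e-4)
    p10 = float(np.clip(np.exp(intercept), 1e-3, 10.0))

    if fix_p2 is not None:
        x0 = [p10, k0]
        lower, upper = [1e-6, 1e-8], [50.0, 50.0]

        def model(x):
            return x[0] * np.exp(-x[1] * np.maximum(c, 0.0) ** fix_p2)
    else:
        x0 = [p10, k0, p2_0]
        lower, upper = [1e-6, 1e-8, 0.05], [50.0, 50.0, 2.0]

        def model(x):
            return x[0] * np.exp(-x[1] * np.maximum(c, 0.0) ** x[2])

    res = optimize.least_squares(
        lambda x: model(x) - y, x0=x0, bounds=(lower, upper), xtol=1e-14,
        ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise ConvergenceError(
            f"profile fit did not converge: {res.message} (x={res.x})"
        )
    p1, k = float(res.x[0]), float(res.x[1])
    p2 = float(fix_p2) if fix_p2 is not None else float(res.x[2])
    rmse = float(np.sqrt(np.mean(res.fun**2))) * i0
    return ProfileParams(p1=p1, p2=p2, k=k, ka=ka), rmse


def absorbed_light(
    c,
    w_u: float,
    i0: float,
    params: ProfileParams,
    chl: float,
) -> np.ndarray | float:
    """Absorbed flux density per unit Chl for two-sided incidence.

    ``I_a(c) = I0 p1 ka (w_u exp(-k c**p2) + (1-w_u) exp(-k (Chl-c)**p2))``
    in umol photons s-1 per (ug Chl cm-2) per m2 ground, for ``i0`` in
    umol m-2 s-1 summed over both leaf sides.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < -1e-9) or np.any(c_arr > chl * (1 + 1e-9)):
        raise InvalidInputError("c must lie within [0, Chl]")
    if not 0.0 <= w_u <= 1.0:
        raise InvalidInputError("w_u must lie in [0, 1]")
    cc = np.clip(c_arr, 0.0, chl)
    val = i0 * params.p1ka * (
        w_u * np.exp(-params.k * cc**params.p2)
        + (1.0 - w_u) * np.exp(-params.k * (chl - cc) ** params.p2)
    )
    return float(val) if np.isscalar(c) else val


def normalized_capacity_curve(
    c,
    params: ProfileParams,
    p3: float,
    w_u_g: float,
    chl: float,
) -> np.ndarray | float:
    """Normalized capacity profile ``C_n(c)`` with modified extinction.

    The capacity of electron transport follows the absorbed-light shape
    with extinction ``k' = p3 k``; normalizing at the adaxial surface gives
    ``C_n(c) = I_a(c, w_u_g, 1, k')/I_a(0, w_u_g, 1, k')`` with
    ``C_n(0) = 1`` by construction.
    """
    if p3 <= 0:
        raise InvalidInputError("p3 must be positive")
    mod = params.with_k(p3 * params.k)
    top = absorbed_light(0.0, w_u_g, 1.0, mod, chl)
    return absorbed_light(c, w_u_g, 1.0, mod, chl) / top


def leaf_profile_pipeline(
    traits: LeafTraits,
    grid: SpectralGrid | None = None,
    coefficient_table=None,
    structure: float = 1.0,
    seed: int = 0,
    jitter_sd: float = 0.05,
    fix_p2: float | None = constants.P2_DEFAULT,
    n_c: int = 101,
    illuminant: Illuminant | None = None,
) -> dict:
    """Full optics-to-profile chain for one leaf.

    Generates (or would accept) a bulk leaf spectrum, inverts reflectance
    and transmittance per wavelength to two-stream coefficients, solves the
    forward profiles, integrates them under the daylight illuminant with
    photosynthetic effectiveness weighting, and fits the stretched
    exponential.  Returns the quantities the trait surrogate is trained on
    (``p1ka``, ``k``, broadband ``T``) plus diagnostics.
    """
    grid = grid or SpectralGrid.par()
    illuminant = illuminant or Illuminant.d55(grid)
    spectrum = synth_leaf_spectrum(
        traits, coefficient_table=coefficient_table, structure=structure,
        seed=seed, grid=grid, jitter_sd=jitter_sd,
    )
    iface = diffuse_interface_reflectance(spectrum.n)
    coeffs = invert_RT(spectrum.R, spectrum.T, iface, traits.chl)
    sol = TwoStreamSolution(
        coeffs.k_s, coeffs.k_a, iface.r_e, iface.r_i, traits.chl
    )
    prof = sol.profile(n_c)
    depths = leaf_optical_depths(
        traits.chl, traits.car, traits.lma, grid, coefficient_table, structure
    )
    tau_a = np.maximum(depths["tau_a"], 1e-300)
    fractions = {
        "chl": depths["tau_chl"] / tau_a,
        "car": depths["tau_car"] / tau_a,
        "other": depths["tau_dm"] / tau_a,
    }
    I_c, ka_eff = broadband_profile(
        prof, coeffs, illuminant, absorption_fractions=fractions
    )
    params, rmse = fit_profile_params(
        I_c, prof.c, traits.chl, fix_p2=fix_p2, ka=ka_eff
    )
    T_broadband = float(np.sum(illuminant.weights * spectrum.T))
    return {
        "traits": traits,
        "spectrum": spectrum,
        "coeffs": coeffs,
        "iface": iface,
        "profile_c": prof.c,
        "profile_I": I_c,
        "params": params,
        "rmse": rmse,
        "p1ka": params.p1 * ka_eff,
        "k": params.k,
        "p2": params.p2,
        "ka": ka_eff,
        "T": T_broadband,
    }
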