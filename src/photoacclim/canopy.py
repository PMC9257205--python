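"""Canopy-scale field computations for a vertically grown crop.

Per-layer leaf area and overlying leaf-area index, chlorophyll estimation
from four-band remission readings, vertical chlorophyll and leaf-mass-area
profiles over relative insertion height, and the conversion of net
assimilation to whole-leaf electron transport rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from . import constants
from .exceptions import ConvergenceError, InvalidInputError

__all__ = [
    "CanopyLayerState",
    "RemissionReadings",
    "leaf_area",
    "lai_above",
    "chl_from_remission",
    "robust_profile_fit",
    "chl_profile_adjust",
    "lma_profile",
    "jleaf_from_gas_exchange",
]


@dataclass(frozen=True)
class CanopyLayerState:
    """One vertical canopy layer (index 1 = top of the counted stack)."""

    index: int
    s_l: float  # one-sided area of a single leaf, cm2
    s_p: float = constants.S_P_DEFAULT  # ground area per plant, cm2
    z: float = 0.5  # relative insertion, 0 = bottom

    def __post_init__(self):
        if self.s_l <= 0 or self.s_p <= 0:
            raise InvalidInputError("areas must be positive")
        if not 0.0 <= self.z <= 1.0:
            raise InvalidInputError("relative insertion must lie in [0, 1]")


@dataclass(frozen=True)
class RemissionReadings:
    """Remission (diffuse reflectance) at 713, 709, 703 and 699 nm."""

    r713: float
    r709: float
    r703: float
    r699: float

    def __post_init__(self):
        if min(self.r713, self.r709, self.r703, self.r699) <= 0:
            raise InvalidInputError("remission readings must be positive")


def leaf_area(length_cm: float, width_cm: float) -> float:
    """Single-leaf one-sided area (cm2) from length and width:
    ``S_L = 0.2568 W L + 11.725``.  At L = W = 0 this returns the
    regression intercept, an extrapolation outside the calibration range."""
    if length_cm < 0 or width_cm < 0:
        raise InvalidInputError("leaf dimensions must be nonnegative")
    return (
        constants.LEAF_AREA_SLOPE * width_cm * length_cm
        + constants.LEAF_AREA_INTERCEPT
    )


def lai_above(
    layer_leaf_areas, s_p: float = constants.S_P_DEFAULT
) -> float:
    """Overlying leaf-area index for the last (target) layer.

    ``layer_leaf_areas`` is ordered top -> target; every layer strictly
    above the target contributes both of its leaves (2 S_L), while the
    target layer contributes one: ``LAI_t = (sum 2 S_L,above + S_L,i)/S_p``.
    """
    areas = np.asarray(layer_leaf_areas, dtype=float)
    if areas.size == 0:
        raise InvalidInputError("need at least the target layer")
    if s_p <= 0:
        raise InvalidInputError("S_p must be positive")
    return float((2.0 * areas[:-1].sum() + areas[-1]) / s_p)


def chl_from_remission(r: RemissionReadings, tol: float = 1e-9) -> float:
    """Total chlorophyll (ug cm-2) from a four-band remission ratio:
    ``Chl = 57.74 (R713 - R709)/(R703 - R699) - 18.11``.

    Negative results (possible for senesced or out-of-calibration leaves)
    are clamped to zero with a warning.
    """
    denom = r.r703 - r.r699
    if abs(denom) <= tol:
        raise InvalidInputError(
            "remission denominator R703 - R699 is degenerate"
        )
    chl = (
        constants.CHL_REMISSION_SLOPE * (r.r713 - r.r709) / denom
        + constants.CHL_REMISSION_INTERCEPT
    )
    if chl < 0:
        warnings.warn(
            f"remission calibration gave Chl = {chl:.2f} ug/cm2; clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return float(chl)


def robust_profile_fit(
    z,
    chl_obs,
    degree: int = 1,
    tuning: float = 4.685,
    max_iter: int = 100,
) -> dict:
    """Robust polynomial fit of a vertical trait profile.

    Iteratively reweighted least squares with Tukey bisquare weights
    (conventional tuning constant 4.685), polynomial in relative insertion
    ``z``.  Returns coefficients (ascending powers), robust weights and the
    fitted values.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(chl_obs, dtype=float)
    if degree not in (1, 2):
        raise InvalidInputError("degree must be 1 or 2")
    if z.size < degree + 2:
        raise InvalidInputError(f"need at least {degree + 2} points")
    X = np.vander(z, degree + 1, increasing=True)
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=tuning))
    try:
        res = model.fit(maxiter=max_iter)
    except Exception as exc:  # pragma: no cover - statsmodels internal
        raise ConvergenceError(f"robust fit failed: {exc}") from exc
    return {
        "coefficients": np.asarray(res.params, dtype=float),
        "weights": np.asarray(res.weights, dtype=float),
        "fitted": np.asarray(res.fittedvalues, dtype=float),
        "predict": lambda zz: np.vander(
            np.asarray(zz, float), degree + 1, increasing=True
        ) @ res.params,
    }


def chl_profile_adjust(
    z: float,
    chl_mean_at_z: float,
    ppfd_expansion: float,
    ppfd_mean: float,
    m: float = constants.M_CHL_DEFAULT,
) -> float:
    """Adjust the mean Chl(z) profile for light received during expansion.

    ``Chl' = Chl(z) + m (PPFD - mean PPFD) * 2 max(0, z - 0.5)``: leaves
    that expanded under above-average light carry extra chlorophyll, an
    effect that tapers linearly to nothing at mid-canopy and below.
    Continuous at z = 0.5.
    """
    if not 0.0 <= z <= 1.0:
        raise InvalidInputError("z must lie in [0, 1]")
    return chl_mean_at_z + m * (ppfd_expansion - ppfd_mean) * 2.0 * max(
        0.0, z - 0.5
    )


def lma_profile(
    z,
    lma_bottom: float,
    gain: float = 1.0,
    rate: float = 2.0,
) -> np.ndarray | float:
    """Vertical leaf-mass-per-area profile (starch-free), g m-2.

    Monotone exponential saturation anchored at the bottom of the canopy:
    ``LMA(z) = lma_bottom (1 + gain (1 - exp(-rate z)))``.  ``gain`` sets
    the total top/bottom contrast, ``rate`` how quickly it develops with
    insertion height.
    """
    zz = np.asarray(z, dtype=float)
    if np.any(zz < 0) or np.any(zz > 1):
        raise InvalidInputError("z must lie in [0, 1]")
    if lma_bottom <= 0:
        raise InvalidInputError("lma_bottom must be positive")
    if gain < 0 or rate <= 0:
        raise InvalidInputError("gain must be >= 0 and rate > 0")
    out = lma_bottom * (1.0 + gain * (1.0 - np.exp(-rate * zz)))
    return float(out) if np.isscalar(z) else out


def jleaf_from_gas_exchange(
    an: float,
    rd: float,
    ci: float,
    gamma_star: float = constants.GAMMA_STAR_DEFAULT,
) -> float:
    """Whole-leaf electron transport rate from gas exchange, umol e- m-2 s-1.

    ``J = (A_n + 0.5 R_d)(4.5 C_i + 10.5 Gamma*)/((1 - Gamma*/C_i) C_i)``
    assuming day respiration at half the dark rate.  Requires
    ``C_i > Gamma*`` (otherwise the RuBP-limited relation is undefined).
    """
    if ci <= gamma_star:
        raise InvalidInputError(
            f"C_i ({ci:g} ppm) must exceed the compensation point "
            f"Gamma* ({gamma_star:g} ppm)"
        )
    return (
        (an + 0.5 * rd)
        * (4.5 * ci + 10.5 * gamma_star)
        / ((1.0 - gamma_star / ci) * ci)
    )
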