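"""Photosynthetic electron transport over the mesophyll depth.

The local electron transport rate per unit chlorophyll ``J_c(c)`` responds
to absorbed light ``I_a(c)`` through a non-rectangular hyperbola (NRH) with
curvature ``theta`` and saturates at a capacity ``J_c,max(c)``.  The
capacity itself follows the absorbed-light profile of the *growth*
environment (characteristic acclimation intensity ``I*``, upper-side
fraction ``w_u,g`` and a rescaled extinction ``k' = p3 k``), clamped
between ontogenetic limits ``J_c,max,mn(t) <= J_c,max,mx(t)``::

    J_c,max(c) = min{J_c,max,mx, max[J_c,max,mn, phi I_a(c, w_u,g, I*, k')]}

The whole-leaf rate integrates ``J_c`` over cumulative chlorophyll; the
capacity integral times a proportionality ``p4`` gives the maximum
carboxylation rate.  Rates per unit chlorophyll carry units of
mmol e- (mol Chl)-1 s-1; leaf-area rates are umol e- m-2 s-1, converted
with a configurable chlorophyll a+b molar mass (default 900 g mol-1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import optimize

from . import constants
from .exceptions import InvalidInputError
from .profile import ProfileParams, absorbed_light

__all__ = [
    "ETRParams",
    "quantum_efficiency",
    "cuvette_correction",
    "capacity_profile",
    "jc_rate",
    "integrate_jleaf",
    "operational_jmax",
    "vcmax",
    "jleaf_batch",
    "capacity_integral_batch",
]


def quantum_efficiency(f_cyc: float, phi_2m: float) -> float:
    """PSII quantum efficiency of electron transport for absorbed photons.

    ``phi = (1 - f_cyc) / (1 + (1 - f_cyc)/Phi_2m)`` with cyclic electron
    flow fraction ``f_cyc`` and maximum PSII electron-transport efficiency
    ``Phi_2m``.  With ``f_cyc = 0`` and ``Phi_2m = 0.88`` this gives 0.468.
    """
    if not 0.0 <= f_cyc <= 1.0:
        raise InvalidInputError("f_cyc must lie in [0, 1]")
    if not 0.0 < phi_2m <= 1.0:
        raise InvalidInputError("phi_2m must lie in (0, 1]")
    return (1.0 - f_cyc) / (1.0 + (1.0 - f_cyc) / phi_2m)


def cuvette_correction(
    T: float, r_ch: float = constants.R_CH_DEFAULT, i0: float = 1.0
) -> tuple[float, float]:
    """Upper-side fraction and total intensity in a gas-exchange cuvette.

    With one-sided actinic light, the fraction ``T`` transmitted through the
    leaf is partly reflected back by the chamber's lower wall (reflectance
    ``r_ch``); neglecting multiple reflections the leaf receives
    ``I0' = I0 (1 + T r_ch)`` in total with upper-side fraction
    ``w_u,m = 1/(1 + T r_ch)``.
    """
    if not 0.0 <= T < 1.0:
        raise InvalidInputError("T must lie in [0, 1)")
    if not 0.0 <= r_ch <= 1.0:
        raise InvalidInputError("r_ch must lie in [0, 1]")
    w_u_m = 1.0 / (1.0 + T * r_ch)
    return w_u_m, i0 * (1.0 + T * r_ch)


@dataclass(frozen=True)
class ETRParams:
    """Electron-transport parameter bundle.

    phi            : mol e- per mol absorbed photons
    theta          : NRH curvature, (0, 1]
    p3             : capacity-profile extinction scaling (k' = p3 k)
    jc_max_mn/mx   : ontogenetic capacity limits, mmol e- (mol Chl)-1 s-1
    i_star         : characteristic acclimation intensity, umol m-2 s-1
    w_u_g / w_u_m  : upper-side light fractions, growth / measurement
    p4             : V_cmax per unit capacity integral, dimensionless
    chl_molar_mass : g mol-1 for converting Chl mass to moles
    """

    phi: float = constants.PHI_DEFAULT
    theta: float = constants.THETA_DEFAULT
    p3: float = constants.P3_DEFAULT
    jc_max_mn: float = 0.0
    jc_max_mx: float = np.inf
    i_star: float = 300.0
    w_u_g: float = 0.9
    w_u_m: float = 1.0
    p4: float = constants.P4_DEFAULT
    chl_molar_mass: float = constants.CHL_MOLAR_MASS_DEFAULT

    def __post_init__(self):
        if not 0.0 < self.theta <= 1.0:
            raise InvalidInputError("theta must lie in (0, 1]")
        if not 0.0 <= self.phi <= 0.5:
            raise InvalidInputError("phi must lie in [0, 0.5]")
        if not (0.0 <= self.jc_max_mn <= self.jc_max_mx):
            raise InvalidInputError("need 0 <= jc_max_mn <= jc_max_mx")
        for name in ("w_u_g", "w_u_m"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidInputError(f"{name} must lie in [0, 1]")

    def replace(self, **kwargs) -> "ETRParams":
        return replace(self, **kwargs)

    @property
    def unit_conv(self) -> float:
        """umol m-2 s-1 per [mmol (mol Chl)-1 s-1 * ug cm-2]."""
        return 10.0 / self.chl_molar_mass


def capacity_profile(
    c,
    params: ETRParams,
    profile: ProfileParams,
    chl: float,
) -> np.ndarray | float:
    """Local capacity ``J_c,max(c)`` in mmol e- (mol Chl)-1 s-1.

    Light-set value ``phi * I_a(c, w_u_g, I*, k')`` with the growth-side
    geometry and the rescaled extinction ``k' = p3 k``, clamped between the
    ontogenetic limits.
    """
    mod = profile.with_k(params.p3 * profile.k)
    ia = absorbed_light(c, params.w_u_g, params.i_star, mod, chl)
    light_set = params.phi * ia * (params.chl_molar_mass / 10.0)
    return np.minimum(
        params.jc_max_mx, np.maximum(params.jc_max_mn, light_set)
    )


def jc_rate(ia, jc_max, phi: float, theta: float):
    """Non-rectangular hyperbola for the local electron transport rate.

    Smaller root of ``theta J^2 - (phi Ia + Jmax) J + phi Ia Jmax = 0``,
    evaluated in the cancellation-free form
    ``J = 2 x y / (s + sqrt((x - y)^2 + 4 x y (1 - theta)))`` with
    ``x = phi Ia``, ``y = Jmax``, ``s = x + y``; at ``theta = 1`` this is
    exactly ``min(x, y)`` and it remains stable as ``theta -> 0``.
    ``ia`` must be on the same per-Chl unit scale as ``jc_max``.
    """
    if not 0.0 < theta <= 1.0:
        raise InvalidInputError("theta must lie in (0, 1]")
    x = phi * np.asarray(ia, dtype=float)
    y = np.asarray(jc_max, dtype=float)
    disc = (x - y) ** 2 + 4.0 * x * y * (1.0 - theta)
    denom = x + y + np.sqrt(disc)
    out = np.where(denom > 0, 2.0 * x * y / np.where(denom > 0, denom, 1.0), 0.0)
    return float(out) if np.isscalar(ia) and np.isscalar(jc_max) else out


def _clamp_breakpoints(params: ETRParams, profile: ProfileParams, chl: float
                       ) -> list[float]:
    """Depths where the light-set capacity crosses a clamp limit."""
    mod = profile.with_k(params.p3 * profile.k)
    conv = params.chl_molar_mass / 10.0

    def g(c):
        return params.phi * conv * absorbed_light(
            np.clip(c, 0.0, chl), params.w_u_g, params.i_star, mod, chl
        )

    pts: list[float] = []
    cs = np.linspace(0.0, chl, 257)
    vals = g(cs)
    for limit in (params.jc_max_mn, params.jc_max_mx):
        if not np.isfinite(limit) or limit <= 0:
            continue
        sign = np.sign(vals - limit)
        for i in np.flatnonzero(np.diff(sign) != 0):
            try:
                pts.append(
                    float(optimize.brentq(
                        lambda c: g(c) - limit, cs[i], cs[i + 1], xtol=1e-10
                    ))
                )
            except ValueError:
                pass
    return sorted(set(pts))


def _gl_nodes(a: float, b: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = leggauss(n)
    return 0.5 * (b - a) * (x + 1.0) + a, 0.5 * (b - a) * w


def _segments(chl: float, breaks: list[float]) -> list[tuple[float, float]]:
    edges = [0.0] + [b for b in breaks if 1e-12 < b < chl - 1e-12] + [chl]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def integrate_jleaf(
    i0: float,
    chl: float,
    params: ETRParams,
    profile: ProfileParams,
    n_nodes: int = 64,
    split: bool = True,
) -> float:
    """Whole-leaf electron transport rate, umol e- m-2 s-1.

    ``J_leaf = integral over c of J_c(c) dc`` with the NRH integrand:
    absorbed light at measurement conditions ``(w_u_m, i0, k)`` and capacity
    from the growth-side profile.  Fixed-order Gauss-Legendre quadrature,
    by default split at the depths where the capacity clamps switch so the
    integrand is smooth on every panel.
    """
    if chl <= 0:
        raise InvalidInputError("Chl must be positive")
    conv = params.chl_molar_mass / 10.0

    def integrand(c):
        ia = absorbed_light(c, params.w_u_m, i0, profile, chl) * conv
        jmax = capacity_profile(c, params, profile, chl)
        return jc_rate(ia, jmax, params.phi, params.theta)

    segs = _segments(chl, _clamp_breakpoints(params, profile, chl)) if split \
        else [(0.0, chl)]
    total = 0.0
    for a, b in segs:
        c, w = _gl_nodes(a, b, n_nodes)
        total += float(np.sum(w * integrand(c)))
    return total * params.unit_conv


def operational_jmax(
    params: ETRParams,
    profile: ProfileParams,
    chl: float,
    i0_ref: float = constants.I0_MEASUREMENT_DEFAULT,
    T: float | None = None,
    r_ch: float = constants.R_CH_DEFAULT,
) -> float:
    """Operational J_max as the leaf rate at the reference measurement PPFD.

    The value retrieved from an A/Ci protocol corresponds to the leaf rate
    at the (cuvette-corrected) measurement intensity rather than the
    mathematical capacity integral.  When the leaf broadband transmittance
    ``T`` is given, the chamber correction sets ``w_u_m`` and scales
    ``i0_ref``; otherwise ``params.w_u_m`` and ``i0_ref`` are used as-is.
    """
    if i0_ref <= 0:
        raise InvalidInputError("i0_ref must be positive")
    if T is not None:
        w_u_m, i0_ref = cuvette_correction(T, r_ch, i0_ref)
        params = params.replace(w_u_m=w_u_m)
    return integrate_jleaf(i0_ref, chl, params, profile)


def vcmax(params: ETRParams, profile: ProfileParams, chl: float) -> float:
    """Maximum carboxylation rate, umol CO2 m-2 s-1.

    Proportional to the capacity integral over cumulative chlorophyll:
    ``V_cmax = p4 * integral of J_c,max(c) dc`` (growth-side profile).
    """
    if params.p4 <= 0:
        raise InvalidInputError("p4 must be positive")
    segs = _segments(chl, _clamp_breakpoints(params, profile, chl))
    total = 0.0
    for a, b in segs:
        c, w = _gl_nodes(a, b, 64)
        total += float(np.sum(w * capacity_profile(c, params, profile, chl)))
    return params.p4 * total * params.unit_conv


# ---------------------------------------------------------------------------
# vectorized kernels for calibration fits (one row per observation)
# ---------------------------------------------------------------------------


def _ia_batch(c, w_u, i0, p1ka, k, p2, chl):
    """Absorbed light on node matrix ``c`` (n_obs, n_nodes); leaf-wise
    scalars broadcast as (n_obs, 1)."""
    return i0 * p1ka * (
        w_u * np.exp(-k * c**p2)
        + (1.0 - w_u) * np.exp(-k * (chl - c) ** p2)
    )


def _batch_nodes(chl: np.ndarray, n_nodes: int):
    x, w = leggauss(n_nodes)
    c = 0.5 * chl[:, None] * (x[None, :] + 1.0)
    wq = 0.5 * chl[:, None] * w[None, :]
    return c, wq


def jleaf_batch(
    i0,
    chl,
    p1ka,
    k,
    p2,
    i_star,
    jc_max_mn,
    jc_max_mx,
    phi: float,
    theta: float,
    p3: float,
    w_u_g,
    w_u_m,
    molar_mass: float = constants.CHL_MOLAR_MASS_DEFAULT,
    n_nodes: int = 96,
) -> np.ndarray:
    """Vectorized whole-leaf electron transport for fitting workloads.

    All leaf-wise arguments broadcast to a common 1-D shape; returns
    umol e- m-2 s-1 per observation.  Plain fixed-order quadrature (no
    panel splitting) — with 96 nodes the kink error of the clamped
    integrand is far below observation noise.
    """
    (i0, chl, p1ka, k, i_star, jmn, jmx, wug, wum) = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(v, dtype=float)) for v in
          (i0, chl, p1ka, k, i_star, jc_max_mn, jc_max_mx, w_u_g, w_u_m))
    )
    conv = molar_mass / 10.0
    c, wq = _batch_nodes(chl, n_nodes)
    col = lambda v: v[:, None]
    ia_meas = _ia_batch(c, col(wum), col(i0), col(p1ka), col(k), p2, col(chl))
    ia_grow = _ia_batch(
        c, col(wug), col(i_star), col(p1ka), p3 * col(k), p2, col(chl)
    )
    jmax = np.minimum(col(jmx), np.maximum(col(jmn), phi * conv * ia_grow))
    jc = jc_rate(conv * ia_meas, jmax, phi, theta)
    return np.sum(wq * jc, axis=1) * (10.0 / molar_mass)


def capacity_integral_batch(
    chl,
    p1ka,
    k,
    p2,
    i_star,
    jc_max_mn,
    jc_max_mx,
    phi: float,
    p3: float,
    w_u_g,
    molar_mass: float = constants.CHL_MOLAR_MASS_DEFAULT,
    n_nodes: int = 96,
) -> np.ndarray:
    """Vectorized capacity integral (the quantity ``V_cmax/p4``),
    umol e- m-2 s-1 per observation."""
    (chl, p1ka, k, i_star, jmn, jmx, wug) = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(v, dtype=float)) for v in
          (chl, p1ka, k, i_star, jc_max_mn, jc_max_mx, w_u_g))
    )
    conv = molar_mass / 10.0
    c, wq = _batch_nodes(chl, n_nodes)
    col = lambda v: v[:, None]
    ia_grow = _ia_batch(
        c, col(wug), col(i_star), col(p1ka), p3 * col(k), p2, col(chl)
    )
    jmax = np.minimum(col(jmx), np.maximum(col(jmn), phi * conv * ia_grow))
    return np.sum(wq * jmax, axis=1) * (10.0 / molar_mass)
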