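"""Intra-leaf two-stream radiation transfer.

The mesophyll is treated as a scattering/absorbing slab whose depth
coordinate is cumulative chlorophyll content ``c`` (ug cm-2), running from 0
at the adaxial mesophyll surface down to the total content ``Chl``.  Two
diffuse fluxes are propagated, downward ``I_d`` and upward ``I_u``::

    dI_d/dc = -(k_s + k_a) I_d + k_s I_u
    dI_u/dc = +(k_s + k_a) I_u - k_s I_d

with scattering and absorption coefficients per unit cumulative chlorophyll
(cm2 ug-1) and boundary conditions coupling the internal fluxes to the
epidermis through diffuse Fresnel reflectances: externally ``r_e``
(air -> epidermis) and internally ``r_i`` (epidermis -> air)::

    I_d(0)   = (1 - r_e) + r_i I_u(0)
    I_u(Chl) = r_i I_d(Chl)

for unit incident diffuse flux on the upper side.  Bulk leaf reflectance and
transmittance follow as ``R = I_u(0) (1 - r_i) + r_e`` and
``T = I_d(Chl) (1 - r_i)``.

The constant-coefficient system has a closed-form solution; this module
provides the forward solve, its inversion (bulk ``R, T`` to ``k_s, k_a``),
the hemispherical Fresnel integrals for ``r_e``/``r_i``, and a parametric
synthetic leaf-spectrum generator with a hook for measured specific
absorption coefficient tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import optimize

from .exceptions import InvalidInputError, NoSolutionError

__all__ = [
    "SpectralGrid",
    "LeafSpectrum",
    "TwoStreamCoefficients",
    "InterfaceReflectances",
    "RadiationProfile",
    "TwoStreamSolution",
    "diffuse_interface_reflectance",
    "solve_two_stream",
    "invert_RT",
    "synth_leaf_spectrum",
    "default_absorption_table",
]

# Optical depth of absorption (path-amplified) below which the slab is
# treated as conservatively scattering; keeps the closed form well posed.
_CONSERVATIVE_TOL = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectralGrid:
    """Ascending wavelength grid (nm) covering at least the PAR band."""

    wavelengths: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise InvalidInputError("wavelength grid must be a 1-D array")
        if np.any(np.diff(w) <= 0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        if w[0] < 350.0 or w[-1] > 800.0:
            raise InvalidInputError("wavelengths must lie within [350, 800] nm")
        object.__setattr__(self, "wavelengths", w)

    @classmethod
    def par(cls, step: float = 5.0) -> "SpectralGrid":
        """The 400-700 nm photosynthetically active band."""
        n = int(round((700.0 - 400.0) / step))
        return cls(np.linspace(400.0, 700.0, n + 1))

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass
class LeafSpectrum:
    """Bulk hemispherical reflectance/transmittance and refractive index."""

    wavelengths: np.ndarray
    R: np.ndarray
    T: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        for name in ("wavelengths", "R", "T", "n"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.R.shape == self.T.shape == self.n.shape):
            raise InvalidInputError("R, T, n must share one shape")
        if np.any(self.R < 0) or np.any(self.T < 0):
            raise InvalidInputError("R and T must be nonnegative")
        if np.any(self.R + self.T > 1.0 + 1e-12):
            raise InvalidInputError("R + T must not exceed 1")
        if np.any(self.n < 1.0):
            raise InvalidInputError("refractive index must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "R": self.R, "T": self.T,
             "n_refr": self.n}
        )


@dataclass
class TwoStreamCoefficients:
    """Scattering/absorption per unit cumulative Chl (cm2 ug-1)."""

    k_s: np.ndarray | float
    k_a: np.ndarray | float

    def __post_init__(self):
        ks = np.asarray(self.k_s, dtype=float)
        ka = np.asarray(self.k_a, dtype=float)
        if np.any(ks < 0) or np.any(ka < 0):
            raise InvalidInputError("two-stream coefficients must be >= 0")
        self.k_s, self.k_a = ks, ka


@dataclass
class InterfaceReflectances:
    """Diffuse boundary reflectances at the epidermis."""

    r_e: np.ndarray | float
    r_i: np.ndarray | float

    def __post_init__(self):
        re = np.asarray(self.r_e, dtype=float)
        ri = np.asarray(self.r_i, dtype=float)
        if np.any(re < 0) or np.any(re >= 1) or np.any(ri < 0) or np.any(ri >= 1):
            raise InvalidInputError("interface reflectances must lie in [0, 1)")
        self.r_e, self.r_i = re, ri

    @classmethod
    def none(cls) -> "InterfaceReflectances":
        return cls(0.0, 0.0)


@dataclass
class RadiationProfile:
    """Downward/upward diffuse fluxes on a cumulative-Chl grid.

    Fluxes are fractions of unit incident flux; arrays have shape
    ``(n_c,)`` for a single wavelength or ``(n_c, n_lambda)``.
    """

    c: np.ndarray
    I_d: np.ndarray
    I_u: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.I_d + self.I_u


# ---------------------------------------------------------------------------
# diffuse Fresnel boundary reflectances
# ---------------------------------------------------------------------------


def _fresnel_unpolarized(mu1: np.ndarray, n1: float, n2: float) -> np.ndarray:
    """Unpolarized Fresnel reflectance for cosine of incidence ``mu1``."""
    mu1 = np.asarray(mu1, dtype=float)
    s2 = (n1 / n2) * np.sqrt(np.clip(1.0 - mu1**2, 0.0, 1.0))
    tir = s2 > 1.0
    mu2 = np.sqrt(np.clip(1.0 - np.minimum(s2, 1.0) ** 2, 0.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = ((n1 * mu1 - n2 * mu2) / (n1 * mu1 + n2 * mu2)) ** 2
        rp = ((n2 * mu1 - n1 * mu2) / (n2 * mu1 + n1 * mu2)) ** 2
    out = 0.5 * (rs + rp)
    return np.where(tir, 1.0, out)


def _composite_gauss(theta_max: float, nodes: int):
    """Composite Gauss-Legendre nodes/weights on [0, theta_max] built from
    64-point panels (total node count >= ``nodes``)."""
    x, w = leggauss(64)
    panels = max(int(np.ceil(nodes / 64)), 1)
    edges = np.linspace(0.0, theta_max, panels + 1)
    half = 0.5 * np.diff(edges)
    mid = 0.5 * (edges[:-1] + edges[1:])
    theta = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    weights = (half[:, None] * w[None, :]).ravel()
    return theta, weights


def _hemispherical_reflectance(n1: float, n2: float, nodes: int) -> float:
    """Cosine-weighted hemispherical average of Fresnel reflectance.

    ``r = int_0^{pi/2} F(theta) 2 sin(theta) cos(theta) dtheta``; for
    internal incidence the total-internal-reflection cap beyond the critical
    angle is added analytically so the quadrature only sees a smooth
    integrand.
    """
    if n1 > n2:  # internal side: split at the critical angle
        sin_c = n2 / n1
        theta_max = np.arcsin(sin_c)
        tir_part = 1.0 - sin_c**2  # integral of 2 sin cos over the TIR cap
    else:
        theta_max = 0.5 * np.pi
        tir_part = 0.0
    theta, w = _composite_gauss(theta_max, nodes)
    f = _fresnel_unpolarized(np.cos(theta), n1, n2)
    integral = float(np.sum(w * f * 2.0 * np.sin(theta) * np.cos(theta)))
    return integral + tir_part


def diffuse_interface_reflectance(
    n: float | np.ndarray, nodes: int = 10_000
) -> InterfaceReflectances:
    """Diffuse boundary reflectances ``(r_e, r_i)`` from refractive index.

    For perfectly diffuse (isotropic, unpolarized) irradiance the boundary
    reflectance is the Fresnel reflectance averaged over the hemisphere with
    cosine (projected solid angle) weighting.  ``r_e`` is evaluated for
    air -> epidermis incidence and ``r_i`` for the reverse path, which
    includes total internal reflection beyond the critical angle.

    Satisfies the radiance-invariance identity ``1 - r_i = (1 - r_e)/n**2``.
    """
    n_arr = np.atleast_1d(np.asarray(n, dtype=float))
    if np.any(n_arr < 1.0):
        raise InvalidInputError("refractive index must be >= 1")
    re = np.empty_like(n_arr)
    ri = np.empty_like(n_arr)
    # quadrature is reused across identical indices (the common case of a
    # constant n over the grid)
    cache: dict[float, tuple[float, float]] = {}
    for idx, ni in enumerate(n_arr):
        key = float(ni)
        if key not in cache:
            if ni == 1.0:
                cache[key] = (0.0, 0.0)
            else:
                cache[key] = (
                    _hemispherical_reflectance(1.0, ni, nodes),
                    _hemispherical_reflectance(ni, 1.0, nodes),
                )
        re[idx], ri[idx] = cache[key]
    if np.isscalar(n) or np.asarray(n).ndim == 0:
        return InterfaceReflectances(float(re[0]), float(ri[0]))
    return InterfaceReflectances(re, ri)


# ---------------------------------------------------------------------------
# closed-form two-stream solution
# ---------------------------------------------------------------------------


class TwoStreamSolution:
    """Closed-form solution of the two-stream boundary value problem.

    All coefficient arguments broadcast; the slab thickness ``chl`` is a
    scalar.  Three analytic branches are used: the general case, the pure
    absorber (``k_s = 0``) and the conservative scatterer (``k_a ~ 0``),
    where the general eigen-decomposition degenerates.  The growing
    exponential mode is carried as ``exp(gamma (c - Chl))`` so that large
    optical depths cannot overflow.
    """

    def __init__(self, k_s, k_a, r_e, r_i, chl: float):
        if chl <= 0:
            raise InvalidInputError("Chl must be positive")
        ks, ka, re, ri = np.broadcast_arrays(
            *(np.asarray(v, dtype=float) for v in (k_s, k_a, r_e, r_i))
        )
        if np.any(ks < 0) or np.any(ka < 0):
            raise InvalidInputError("coefficients must be nonnegative")
        self.shape = ks.shape
        self.chl = float(chl)
        self.ks, self.ka, self.re, self.ri = ks, ka, re, ri

        a = ks + ka
        b = ks
        gamma = np.sqrt(ka * (ka + 2.0 * ks))
        pure = b <= 0.0
        cons = (~pure) & (ka * chl * (1.0 + ks * chl) < _CONSERVATIVE_TOL)
        general = ~(pure | cons)
        self._pure, self._cons, self._general = pure, cons, general
        self.gamma = gamma

        safe_b = np.where(b > 0, b, 1.0)
        hm = (a - gamma) / safe_b
        hp = (a + gamma) / safe_b
        E = np.exp(-gamma * chl)
        den = hp - ri
        safe_den = np.where(den != 0.0, den, 1.0)
        M = (1.0 - ri * hm) - E**2 * (1.0 - ri * hp) * (hm - ri) / safe_den
        safe_M = np.where(general & (M != 0.0), M, 1.0)
        C1 = np.where(general, (1.0 - re) / safe_M, 0.0)
        C2 = -C1 * E * (hm - ri) / safe_den
        self._hm, self._hp, self._E = hm, hp, E
        self._C1, self._C2 = C1, C2

        # pure absorber: decoupled Beer-Lambert streams
        Ep = np.exp(-ka * chl)
        Id0_p = (1.0 - re) / (1.0 - ri**2 * Ep**2)
        self._Ep, self._Id0_p = Ep, Id0_p

        # conservative scatterer: linear flux profiles
        t = b * chl * (1.0 - ri)
        Id0_c = (1.0 - re) / ((1.0 - ri) * (1.0 + ri / (1.0 + t)))
        D = Id0_c * (1.0 - ri) / (1.0 + t)
        self._Id0_c, self._D = Id0_c, D

    @property
    def R(self) -> np.ndarray:
        g = self._general
        Iu0_g = self._hm * self._C1 + self._hp * self._C2 * self._E
        Iu0_p = self.ri * self._Id0_p * self._Ep**2
        Iu0_c = self._Id0_c - self._D
        Iu0 = np.where(g, Iu0_g, np.where(self._pure, Iu0_p, Iu0_c))
        return Iu0 * (1.0 - self.ri) + self.re

    @property
    def T(self) -> np.ndarray:
        g = self._general
        IdL_g = self._C1 * self._E + self._C2
        IdL_p = self._Id0_p * self._Ep
        IdL_c = self._Id0_c - self.ks * self.chl * self._D
        IdL = np.where(g, IdL_g, np.where(self._pure, IdL_p, IdL_c))
        return IdL * (1.0 - self.ri)

    def fluxes(self, c) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate ``(I_d(c), I_u(c))`` on an array of depths."""
        c = np.asarray(c, dtype=float)
        if np.any(c < -1e-12) or np.any(c > self.chl * (1 + 1e-12)):
            raise InvalidInputError("c must lie within [0, Chl]")
        cc = c.reshape(c.shape + (1,) * len(self.shape))
        em = np.exp(-self.gamma * cc)
        ep = np.exp(self.gamma * (cc - self.chl))
        Id_g = self._C1 * em + self._C2 * ep
        Iu_g = self._hm * self._C1 * em + self._hp * self._C2 * ep
        Id_p = self._Id0_p * np.exp(-self.ka * cc)
        Iu_p = self.ri * self._Id0_p * self._Ep * np.exp(self.ka * (cc - self.chl))
        Id_c = self._Id0_c - self.ks * self._D * cc
        Iu_c = Id_c - self._D
        Id = np.where(self._general, Id_g, np.where(self._pure, Id_p, Id_c))
        Iu = np.where(self._general, Iu_g, np.where(self._pure, Iu_p, Iu_c))
        return Id, Iu

    def profile(self, n_points: int = 201) -> RadiationProfile:
        c = np.linspace(0.0, self.chl, n_points)
        Id, Iu = self.fluxes(c)
        return RadiationProfile(c=c, I_d=Id, I_u=Iu)


def solve_two_stream(
    coeffs: TwoStreamCoefficients,
    iface: InterfaceReflectances,
    chl: float,
    n_points: int = 201,
) -> tuple[RadiationProfile, np.ndarray, np.ndarray]:
    """Solve the two-stream problem; return profile and bulk ``(R, T)``.

    ``coeffs``/``iface`` may hold scalars (one wavelength) or aligned
    arrays (one solve per wavelength).
    """
    sol = TwoStreamSolution(coeffs.k_s, coeffs.k_a, iface.r_e, iface.r_i, chl)
    prof = sol.profile(n_points)
    R, T = sol.R, sol.T
    if sol.shape == ():
        return prof, float(R), float(T)
    return prof, R, T


# ---------------------------------------------------------------------------
# inversion of bulk (R, T)
# ---------------------------------------------------------------------------


def _rt_residual(ks, ka, re, ri, chl, R_obs, T_obs):
    """Residuals (R - R_obs, log(T/T_obs)); the log keeps the transmittance
    equation well conditioned for optically deep leaves where T underflows
    the absolute tolerance."""
    sol = TwoStreamSolution(np.maximum(ks, 0.0), np.maximum(ka, 0.0), re, ri, chl)
    with np.errstate(divide="ignore"):
        fT = np.log(np.maximum(sol.T, 1e-300)) - np.log(T_obs)
    return sol.R - R_obs, fT


def invert_RT(
    R,
    T,
    iface: InterfaceReflectances,
    chl: float,
    tol: float = 1e-10,
    max_iter: int = 80,
) -> TwoStreamCoefficients:
    """Estimate ``(k_s, k_a)`` from bulk reflectance and transmittance.

    A damped Newton iteration (finite-difference Jacobian, nonnegativity
    projection) starts from the Beer-Lambert heuristic
    ``k_a0 = -ln(T)/Chl``, ``k_s0 = max(R - r_e, 0)/Chl``; stragglers fall
    back to bounded least squares.  Raises :class:`NoSolutionError` when the
    pair is physically inconsistent, naming the violated constraint.
    """
    scalar = np.isscalar(R) and np.isscalar(T)
    R = np.atleast_1d(np.asarray(R, dtype=float))
    T = np.atleast_1d(np.asarray(T, dtype=float))
    re = np.broadcast_to(np.asarray(iface.r_e, dtype=float), R.shape).copy()
    ri = np.broadcast_to(np.asarray(iface.r_i, dtype=float), R.shape).copy()
    if chl <= 0:
        raise InvalidInputError("Chl must be positive")
    if np.any(R < 0) or np.any(T <= 0):
        raise InvalidInputError("need R >= 0 and T > 0")
    if np.any(R + T >= 1.0):
        raise NoSolutionError(
            "R + T >= 1: more flux leaves than enters (energy constraint)"
        )
    if np.any(R < re - 1e-12):
        raise NoSolutionError(
            "R below the external interface reflectance r_e: no nonnegative "
            "scattering coefficient can produce it"
        )

    ka = np.maximum(-np.log(T) / chl, 1e-12)
    ks = np.maximum((R - re) / chl, 0.0)

    active = np.ones(R.shape, dtype=bool)
    for _ in range(max_iter):
        fR, fT = _rt_residual(ks, ka, re, ri, chl, R, T)
        err = np.maximum(np.abs(fR), np.abs(fT))
        active = err > tol
        if not np.any(active):
            break
        # finite-difference Jacobian, vectorized over wavelengths
        hs = 1e-7 * (1.0 + ks)
        ha = 1e-7 * (1.0 + ka)
        fR_s, fT_s = _rt_residual(ks + hs, ka, re, ri, chl, R, T)
        fR_a, fT_a = _rt_residual(ks, ka + ha, re, ri, chl, R, T)
        j11 = (fR_s - fR) / hs
        j12 = (fR_a - fR) / ha
        j21 = (fT_s - fT) / hs
        j22 = (fT_a - fT) / ha
        det = j11 * j22 - j12 * j21
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        dks = -(j22 * fR - j12 * fT) / det
        dka = -(-j21 * fR + j11 * fT) / det
        bad = ~np.isfinite(dks) | ~np.isfinite(dka)
        dks = np.where(bad, 0.0, dks)
        dka = np.where(bad, 0.0, dka)
        # damped update: halve the step until the residual does not grow
        lam = np.where(active, 1.0, 0.0)
        for _damp in range(25):
            ks_new = np.maximum(ks + lam * dks, 0.0)
            ka_new = np.maximum(ka + lam * dka, 1e-14)
            gR, gT = _rt_residual(ks_new, ka_new, re, ri, chl, R, T)
            new_err = np.maximum(np.abs(gR), np.abs(gT))
            worse = active & (new_err > err)
            if not np.any(worse):
                break
            lam = np.where(worse, 0.5 * lam, lam)
        ks, ka = ks_new, ka_new

    fR, fT = _rt_residual(ks, ka, re, ri, chl, R, T)
    err = np.maximum(np.abs(fR), np.abs(fT))
    for idx in np.flatnonzero(err > 1e-8):
        res = optimize.least_squares(
            lambda x, i=idx: np.array(
                _rt_residual(x[0], x[1], re[i], ri[i], chl, R[i], T[i])
            ),
            x0=[max(ks[idx], 1e-6), max(ka[idx], 1e-6)],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        ks[idx], ka[idx] = res.x
        if np.max(np.abs(res.fun)) > 1e-8:
            raise NoSolutionError(
                f"no nonnegative (k_s, k_a) reproduces R={R[idx]:.6g}, "
                f"T={T[idx]:.6g} at Chl={chl:g} (residual "
                f"{np.max(np.abs(res.fun)):.2e})"
            )
    if scalar:
        return TwoStreamCoefficients(float(ks[0]), float(ka[0]))
    return TwoStreamCoefficients(ks, ka)


# ---------------------------------------------------------------------------
# synthetic leaf spectra
# ---------------------------------------------------------------------------


def _gauss(lam: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - mu) / sigma) ** 2)


def _builtin_a_chl(lam: np.ndarray) -> np.ndarray:
    """In-vivo chlorophyll a+b specific absorption, cm2 ug-1 (parametric).

    Sum of Gaussian bands: Soret peak near 430 nm, red peak near 678 nm, a
    weak 625 nm shoulder, and a broad low green-gap floor (pigment packaging
    keeps in-vivo absorption nonzero between the bands).
    """
    return (
        0.055 * _gauss(lam, 430.0, 20.0)
        + 0.046 * _gauss(lam, 678.0, 22.0)
        + 0.011 * _gauss(lam, 625.0, 30.0)
        + 0.0035 * _gauss(lam, 550.0, 90.0)
    )


def _builtin_a_car(lam: np.ndarray) -> np.ndarray:
    """Carotenoid specific absorption, cm2 ug-1: blue bands only."""
    return 0.030 * _gauss(lam, 450.0, 22.0) + 0.028 * _gauss(lam, 482.0, 24.0)


def _builtin_a_dm(lam: np.ndarray) -> np.ndarray:
    """Dry matter (plus bound water) absorption per ug cm-2, weak in the
    visible with a mild rise toward the blue."""
    return 1.5e-5 * (1.0 + 0.8 * (700.0 - lam) / 300.0)


def default_absorption_table(grid: SpectralGrid) -> pd.DataFrame:
    """Built-in specific-absorption table on a grid (documented parametric
    stand-in for a measured leaf-biochemistry coefficient set)."""
    lam = grid.wavelengths
    return pd.DataFrame(
        {
            "wavelength_nm": lam,
            "a_chl": _builtin_a_chl(lam),
            "a_car": _builtin_a_car(lam),
            "a_dm": _builtin_a_dm(lam),
            "n_refr": np.full_like(lam, 1.4),
        }
    )


def _interp_coefficient_table(table: pd.DataFrame, grid: SpectralGrid) -> pd.DataFrame:
    lam = grid.wavelengths
    tw = np.asarray(table["wavelength_nm"], dtype=float)
    if tw.min() > lam[0] + 1e-9 or tw.max() < lam[-1] - 1e-9:
        raise InvalidInputError(
            f"coefficient table covers [{tw.min():g}, {tw.max():g}] nm but the "
            f"grid requires [{lam[0]:g}, {lam[-1]:g}] nm"
        )
    out = {"wavelength_nm": lam}
    for col in ("a_chl", "a_car", "a_dm", "n_refr"):
        out[col] = np.interp(lam, tw, np.asarray(table[col], dtype=float))
    return pd.DataFrame(out)


def leaf_optical_depths(
    chl: float,
    car: float,
    lma: float,
    grid: SpectralGrid,
    coefficient_table: pd.DataFrame | None = None,
    structure: float = 1.0,
) -> dict:
    """Per-wavelength absorption/scattering optical depths for one leaf.

    Absorption is assembled per pigment (``Chl * a_chl + Car * a_car +
    LMA * a_dm`` with LMA converted from g m-2 to ug cm-2); scattering uses
    a flat-spectrum air/cell-wall interface term scaled by ``structure`` and
    leaf dry mass, with a mild ``lambda**-1/2`` slope.  Returns the depths
    and the pigment partition of absorption needed for effectiveness
    weighting downstream.
    """
    table = (
        default_absorption_table(grid)
        if coefficient_table is None
        else _interp_coefficient_table(coefficient_table, grid)
    )
    lam = grid.wavelengths
    lma_ugcm2 = lma * 100.0  # g m-2 -> ug cm-2
    tau_chl = chl * table["a_chl"].to_numpy()
    tau_car = car * table["a_car"].to_numpy()
    tau_dm = lma_ugcm2 * table["a_dm"].to_numpy()
    tau_a = tau_chl + tau_car + tau_dm
    tau_s = structure * (0.4 + 0.5 * (max(lma, 0.0) / 40.0) ** 0.7) * np.sqrt(
        550.0 / lam
    )
    return {
        "wavelengths": lam,
        "tau_a": tau_a,
        "tau_s": tau_s,
        "tau_chl": tau_chl,
        "tau_car": tau_car,
        "tau_dm": tau_dm,
        "n": table["n_refr"].to_numpy(),
    }


def synth_leaf_spectrum(
    traits,
    coefficient_table: pd.DataFrame | None = None,
    structure: float = 1.0,
    seed: int = 0,
    grid: SpectralGrid | None = None,
    jitter_sd: float = 0.05,
) -> LeafSpectrum:
    """Generate a synthetic leaf ``(R, T, n)`` spectrum from bulk traits.

    Stands in for a full leaf optical-properties forward model: per-pigment
    absorption bands and a structure-scaled scattering term are pushed
    through the two-stream solution with diffuse Fresnel boundary
    reflectances.  ``seed`` controls a small lognormal jitter of the
    structural scattering (leaf-to-leaf anatomical variability);
    ``jitter_sd=0`` gives the deterministic mean leaf.
    """
    chl, car, lma = float(traits.chl), float(traits.car), float(traits.lma)
    if min(chl, car, lma) < 0:
        raise InvalidInputError("leaf traits must be nonnegative")
    grid = grid or SpectralGrid.par()
    rng = np.random.default_rng(seed)
    struct_eff = structure * float(np.exp(jitter_sd * rng.standard_normal()))
    depths = leaf_optical_depths(
        chl, car, lma, grid, coefficient_table, struct_eff
    )
    # R and T depend only on optical depths, so a nominal slab thickness
    # keeps the degenerate Chl = 0 case well defined
    chl_depth = chl if chl > 0 else 1.0
    iface = diffuse_interface_reflectance(depths["n"])
    sol = TwoStreamSolution(
        depths["tau_s"] / chl_depth,
        depths["tau_a"] / chl_depth,
        iface.r_e,
        iface.r_i,
        chl_depth,
    )
    return LeafSpectrum(
        wavelengths=grid.wavelengths, R=sol.R, T=sol.T, n=depths["n"]
    )
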