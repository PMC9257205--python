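"""Calibration workflows: nonlinear least-squares fits of the acclimation
model to capacity profiles, light-response curves and canopy J_max/V_cmax
series.

Each workflow is a statsmodels-style model object: construct it from data,
call :meth:`fit`, and receive a results object carrying point estimates,
linearized 95% confidence intervals, RMSE and diagnostics with a
:meth:`summary` table.  Thin functional wrappers (:func:`fit_p3`,
:func:`fit_light_response`, :func:`fit_canopy_acclimation`) preserve a
plain-function surface.

All fits use bounded trust-region least squares with multistart (the best
of several perturbed starting points) and report which parameters were held
fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import constants
from .acclimation import LightHistory, istar_history, istar_step, mean_intercepted_ppfd
from .etr import capacity_integral_batch, cuvette_correction, jleaf_batch
from .exceptions import ConvergenceError, InvalidInputError, NotIdentifiableError
from .profile import ProfileParams, normalized_capacity_curve

__all__ = [
    "FitResult",
    "CapacityProfileModel",
    "LightResponseModel",
    "CanopyAcclimationModel",
    "fit_p3",
    "fit_light_response",
    "fit_canopy_acclimation",
]


@dataclass
class FitResult:
    """Point estimates, uncertainties and diagnostics of one fit."""

    params: dict
    bse: dict
    conf_ints: dict
    rmse: float
    n: int
    converged: bool
    fixed: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def conf_int(self, name: str | None = None):
        if name is not None:
            return self.conf_ints[name]
        return dict(self.conf_ints)

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def summary(self) -> str:
        lines = [
            "Nonlinear least-squares fit",
            f"  n = {self.n}, RMSE = {self.rmse:.4g}, "
            f"converged = {self.converged}",
        ]
        if self.fixed:
            fixed = ", ".join(f"{k}={v:g}" for k, v in self.fixed.items())
            lines.append(f"  fixed: {fixed}")
        lines.append(f"  {'param':<12}{'estimate':>12}{'std err':>12}"
                     f"{'[0.025':>12}{'0.975]':>12}")
        for name, value in self.params.items():
            lo, hi = self.conf_ints.get(name, (np.nan, np.nan))
            se = self.bse.get(name, np.nan)
            lines.append(
                f"  {name:<12}{value:>12.4g}{se:>12.4g}{lo:>12.4g}{hi:>12.4g}"
            )
        for key, value in self.diagnostics.items():
            if np.isscalar(value):
                lines.append(f"  {key} = {value:.6g}" if isinstance(value, float)
                             else f"  {key} = {value}")
        return "\n".join(lines)


def _linearized_ci(res, names, n_obs, alpha=0.05):
    """Std errors and CIs from the Jacobian at the optimum."""
    p = len(names)
    dof = max(n_obs - p, 1)
    sse = float(res.fun @ res.fun)
    s2 = sse / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    bse = dict(zip(names, se))
    cis = {
        name: (res.x[i] - tcrit * se[i], res.x[i] + tcrit * se[i])
        for i, name in enumerate(names)
    }
    return bse, cis


def _multistart_ls(residual, x0, bounds, n_starts, seed, **ls_kwargs):
    """Bounded least squares from the nominal start plus perturbed starts."""
    rng = np.random.default_rng(seed)
    lower, upper = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    x0 = np.asarray(x0, float)
    best = None
    for trial in range(max(n_starts, 1)):
        if trial == 0:
            start = x0
        else:
            jitter = np.exp(rng.normal(0.0, 0.25, size=x0.size))
            start = np.clip(x0 * jitter, lower + 1e-10,
                            np.where(np.isfinite(upper), upper - 1e-10, x0 * 10))
        try:
            res = optimize.least_squares(
                residual, start, bounds=(lower, upper), **ls_kwargs
            )
        except Exception:
            continue
        if best is None or float(res.fun @ res.fun) < float(best.fun @ best.fun):
            best = res
    if best is None:
        raise ConvergenceError("all optimizer starts failed")
    return best


# ---------------------------------------------------------------------------
# capacity-profile scaling p3
# ---------------------------------------------------------------------------


class CapacityProfileModel:
    """Fit the capacity-profile scaling ``p3`` to a normalized profile.

    Observations are relative photosynthetic capacity ``C_n`` against
    cumulative chlorophyll depth ``c``; the model is the normalized
    absorbed-light shape with extinction ``k' = p3 k``.  ``I*`` and the
    scaling ``p1 k_a`` cancel in the normalization and are therefore not
    identifiable from these data.
    """

    def __init__(self, c, cn_obs, profile: ProfileParams, w_u_g: float,
                 chl: float):
        self.c = np.asarray(c, dtype=float)
        self.cn = np.asarray(cn_obs, dtype=float)
        if self.c.size != self.cn.size or self.c.size < 5:
            raise InvalidInputError("need >= 5 aligned (c, C_n) points")
        if np.ptp(self.c) <= 0:
            raise InvalidInputError("capacity observations must span c")
        self.profile = profile
        self.w_u_g = float(w_u_g)
        self.chl = float(chl)

    def predict(self, p3: float) -> np.ndarray:
        return np.asarray(
            normalized_capacity_curve(self.c, self.profile, p3, self.w_u_g,
                                      self.chl)
        )

    def fit(self, p3_0: float = 0.7, n_starts: int = 3, seed: int = 0
            ) -> FitResult:
        if float(np.std(self.cn)) < 1e-12:
            raise NotIdentifiableError(
                "capacity profile is flat; p3 is not identifiable"
            )
        res = _multistart_ls(
            lambda x: self.predict(x[0]) - self.cn,
            [p3_0], ([1e-4], [10.0]), n_starts, seed,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        bse, cis = _linearized_ci(res, ["p3"], self.c.size)
        rmse = float(np.sqrt(np.mean(res.fun**2)))
        return FitResult(
            params={"p3": float(res.x[0])},
            bse=bse, conf_ints=cis, rmse=rmse, n=self.c.size,
            converged=bool(res.success),
            fixed={"w_u_g": self.w_u_g, "k": self.profile.k,
                   "p2": self.profile.p2},
        )


def fit_p3(c, cn_obs, profile: ProfileParams, w_u_g: float, chl: float,
           **fit_kwargs) -> FitResult:
    """Fit ``p3`` for one capacity profile (functional wrapper)."""
    return CapacityProfileModel(c, cn_obs, profile, w_u_g, chl).fit(**fit_kwargs)


def fit_p3_pooled(datasets, **fit_kwargs) -> FitResult:
    """Fit ``p3`` per profile and pool by the mean of the estimates.

    ``datasets`` is an iterable of ``(c, cn_obs, profile, w_u_g, chl)``
    tuples; the pooled result mirrors the practice of averaging per-dataset
    estimates when several independent capacity profiles are available.
    """
    results = [fit_p3(*args, **fit_kwargs) for args in datasets]
    p3s = np.array([r.params["p3"] for r in results])
    pooled = FitResult(
        params={"p3": float(p3s.mean())},
        bse={"p3": float(p3s.std(ddof=1) / np.sqrt(p3s.size))
             if p3s.size > 1 else np.nan},
        conf_ints={"p3": (np.nan, np.nan)},
        rmse=float(np.mean([r.rmse for r in results])),
        n=int(sum(r.n for r in results)),
        converged=all(r.converged for r in results),
        diagnostics={"per_profile_p3": p3s.tolist(),
                     "per_profile": results},
    )
    return pooled


# ---------------------------------------------------------------------------
# light-response curves after a step change in growth irradiance
# ---------------------------------------------------------------------------


class LightResponseModel:
    """Joint fit of electron-transport light-response curves.

    ``data`` holds one row per measured point with columns
    ``treatment, i1, i2, i0, jleaf`` (PPFD in umol m-2 s-1, whole-leaf rate
    in umol e- m-2 s-1); ``leaf_params`` one row per treatment (indexed by
    treatment id) with that leaf's ``chl, p1ka, k, T`` (broadband
    transmittance for the cuvette correction).  Free parameters:
    ``p_i1, p_i2`` of the step-change acclimation-intensity model, the NRH
    curvature ``theta`` and the lower capacity limit ``jc_max_mn``; the
    quantum efficiency, profile scaling ``p3`` and growth-side fraction
    ``w_u_g`` are held fixed.  No upper capacity limit is imposed.
    """

    param_names = ("p_i1", "p_i2", "theta", "jc_max_mn")

    def __init__(self, data: pd.DataFrame, leaf_params: pd.DataFrame,
                 fixed: dict | None = None):
        required = {"treatment", "i1", "i2", "i0", "jleaf"}
        if missing := required - set(data.columns):
            raise InvalidInputError(f"data missing columns: {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.leaf_params = leaf_params
        self.fixed = {
            "phi": constants.PHI_DEFAULT,
            "p3": constants.P3_DEFAULT,
            "w_u_g": 0.9,
            "p2": constants.P2_DEFAULT,
            "r_ch": constants.R_CH_DEFAULT,
        }
        self.fixed.update(fixed or {})
        counts = self.data.groupby("treatment")["i0"].count()
        if (counts < 4).any():
            raise InvalidInputError("need >= 4 intensities per curve")
        # pre-assemble per-row leaf arrays
        rows = self.data["treatment"].to_numpy()
        lp = leaf_params.loc[rows]
        self._chl = lp["chl"].to_numpy(float)
        self._p1ka = lp["p1ka"].to_numpy(float)
        self._k = lp["k"].to_numpy(float)
        T = lp["T"].to_numpy(float)
        corr = np.array([
            cuvette_correction(t, self.fixed["r_ch"], 1.0) for t in T
        ])
        self._w_u_m = corr[:, 0]
        self._i0_scale = corr[:, 1]
        self._i1 = self.data["i1"].to_numpy(float)
        self._i2 = self.data["i2"].to_numpy(float)
        self._i0 = self.data["i0"].to_numpy(float)
        self._y = self.data["jleaf"].to_numpy(float)

    @property
    def n_treatments(self) -> int:
        return self.data[["i1", "i2"]].drop_duplicates().shape[0]

    def predict(self, p_i1: float, p_i2: float, theta: float,
                jc_max_mn: float) -> np.ndarray:
        i_star = p_i1 * (p_i2 * self._i1 + (1.0 - p_i2) * self._i2)
        return jleaf_batch(
            self._i0 * self._i0_scale, self._chl, self._p1ka, self._k,
            self.fixed["p2"], i_star, jc_max_mn, np.inf,
            self.fixed["phi"], theta, self.fixed["p3"],
            self.fixed["w_u_g"], self._w_u_m,
        )

    def fit(self, x0=(1.2, 0.5, 0.9, 200.0), n_starts: int = 3,
            seed: int = 0) -> FitResult:
        if self.n_treatments < 2:
            raise NotIdentifiableError(
                "p_i2 requires >= 2 treatments with distinct (I1, I2)"
            )
        bounds = ([0.05, 0.0, 0.5, 10.0], [5.0, 1.0, 1.0, 1500.0])
        res = _multistart_ls(
            lambda x: self.predict(*x) - self._y,
            x0, bounds, n_starts, seed,
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
            x_scale=[1.0, 0.5, 0.5, 100.0],
        )
        names = list(self.param_names)
        bse, cis = _linearized_ci(res, names, self._y.size)
        return FitResult(
            params=dict(zip(names, map(float, res.x))),
            bse=bse, conf_ints=cis,
            rmse=float(np.sqrt(np.mean(res.fun**2))),
            n=self._y.size, converged=bool(res.success),
            fixed=dict(self.fixed),
        )


def fit_light_response(data, leaf_params, fixed=None, **fit_kwargs) -> FitResult:
    return LightResponseModel(data, leaf_params, fixed).fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# canopy J_max / V_cmax acclimation series
# ---------------------------------------------------------------------------


class CanopyAcclimationModel:
    """Joint fit of canopy J_max/V_cmax observations over time and depth.

    ``obs`` holds one row per leaf per date with columns ``leaf_id, date,
    chl, p1ka, k, T, pr_sum, jmax_obs, vcmax_obs``; ``histories`` maps
    ``leaf_id`` to a :class:`LightHistory` from which the mean intercepted
    PPFD over the previous ``d`` days is computed for each candidate ``d``.
    Free parameters: the acclimation coefficient ``p_i1``
    (``I* = p_i1 * mean PPFD``), the V_cmax proportionality ``p4`` and the
    aging parameters ``p_J0, p_J1`` of the lower capacity limit; the
    averaging depth ``d`` is selected by grid search on the total SSE.
    J_max and V_cmax residuals are stacked with configurable weights
    (default equal).
    """

    param_names = ("p_i1", "p4", "p_j0", "p_j1")

    def __init__(self, obs: pd.DataFrame, histories: dict,
                 fixed: dict | None = None, weights: tuple = (1.0, 1.0)):
        required = {"leaf_id", "date", "chl", "p1ka", "k", "T", "pr_sum",
                    "jmax_obs", "vcmax_obs"}
        if missing := required - set(obs.columns):
            raise InvalidInputError(f"obs missing columns: {sorted(missing)}")
        self.obs = obs.reset_index(drop=True)
        self.histories = histories
        self.weights = weights
        self.fixed = {
            "phi": constants.PHI_DEFAULT,
            "theta": constants.THETA_DEFAULT,
            "p3": constants.P3_DEFAULT,
            "w_u_g": 0.7,
            "p2": constants.P2_DEFAULT,
            "r_ch": constants.R_CH_DEFAULT,
            "n_ratio": constants.N_RATIO_DEFAULT,
            "i0_ref": constants.I0_MEASUREMENT_DEFAULT,
            "k_canopy": constants.K_CANOPY_DEFAULT,
            "age_sign": -1,
        }
        self.fixed.update(fixed or {})
        self._chl = self.obs["chl"].to_numpy(float)
        self._p1ka = self.obs["p1ka"].to_numpy(float)
        self._k = self.obs["k"].to_numpy(float)
        self._pr = self.obs["pr_sum"].to_numpy(float)
        T = self.obs["T"].to_numpy(float)
        corr = np.array([
            cuvette_correction(t, self.fixed["r_ch"], self.fixed["i0_ref"])
            for t in T
        ])
        self._w_u_m = corr[:, 0]
        self._i0_meas = corr[:, 1]
        self._yj = self.obs["jmax_obs"].to_numpy(float)
        self._yv = self.obs["vcmax_obs"].to_numpy(float)
        self._ppfd_cache: dict[int, np.ndarray] = {}

    def ppfd_bar(self, d: int) -> np.ndarray:
        """Per-observation mean intercepted PPFD over the previous d days."""
        if d not in self._ppfd_cache:
            vals = np.empty(len(self.obs))
            for idx, row in self.obs.iterrows():
                vals[idx] = mean_intercepted_ppfd(
                    self.histories[row["leaf_id"]],
                    k_canopy=self.fixed["k_canopy"], d=d,
                    reference_time=row["date"],
                )
            self._ppfd_cache[d] = vals
        return self._ppfd_cache[d]

    def predict(self, p_i1, p4, p_j0, p_j1, d: int):
        """Predicted (jmax, vcmax) arrays for one parameter point."""
        f = self.fixed
        i_star = p_i1 * self.ppfd_bar(d)
        jmn = np.maximum(p_j0 + f["age_sign"] * p_j1 * np.sqrt(self._pr), 0.0)
        jmx = f["n_ratio"] * jmn
        jmax = jleaf_batch(
            self._i0_meas, self._chl, self._p1ka, self._k, f["p2"],
            i_star, jmn, jmx, f["phi"], f["theta"], f["p3"],
            f["w_u_g"], self._w_u_m,
        )
        vc = p4 * capacity_integral_batch(
            self._chl, self._p1ka, self._k, f["p2"], i_star, jmn, jmx,
            f["phi"], f["p3"], f["w_u_g"],
        )
        return jmax, vc

    def _residual(self, x, d):
        jmax, vc = self.predict(*x, d=d)
        wj, wv = self.weights
        return np.concatenate([wj * (jmax - self._yj), wv * (vc - self._yv)])

    def clamp_fraction(self, p_i1, p_j0, p_j1, d: int) -> float:
        """Fraction of observations whose capacity profile is constrained
        from below by the ontogenetic limit."""
        f = self.fixed
        i_star = p_i1 * self.ppfd_bar(d)
        jmn = np.maximum(p_j0 + f["age_sign"] * p_j1 * np.sqrt(self._pr), 0.0)
        conv = constants.CHL_MOLAR_MASS_DEFAULT / 10.0
        # light-set capacity is lowest at the deep (shaded-side) extreme
        cs = np.linspace(0.0, 1.0, 41)
        mins = np.empty(len(self.obs))
        for i in range(len(self.obs)):
            c = cs * self._chl[i]
            kp = f["p3"] * self._k[i]
            ia = i_star[i] * self._p1ka[i] * (
                f["w_u_g"] * np.exp(-kp * c ** f["p2"])
                + (1 - f["w_u_g"]) * np.exp(-kp * (self._chl[i] - c) ** f["p2"])
            )
            mins[i] = (f["phi"] * conv * ia).min()
        return float(np.mean(jmn > mins))

    def fit(self, d_grid=range(1, 8), x0=(0.6, 0.45, 300.0, 7.0),
            n_starts: int = 2, seed: int = 0) -> FitResult:
        d_grid = list(d_grid)
        bars = np.column_stack([self.ppfd_bar(d) for d in d_grid])
        if np.allclose(bars, bars[:, :1], rtol=1e-10, atol=1e-10) and \
                len(d_grid) > 1:
            raise NotIdentifiableError(
                "intercepted-PPFD histories are identical for all candidate "
                "d; the averaging depth is not identifiable"
            )
        bounds = ([0.01, 0.05, 20.0, 0.0], [5.0, 2.0, 2000.0, 100.0])
        fits = {}
        for d in d_grid:
            fits[d] = _multistart_ls(
                lambda x, dd=d: self._residual(x, dd),
                x0, bounds, n_starts, seed,
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                x_scale=[0.5, 0.5, 100.0, 5.0],
            )
        sse = {d: float(r.fun @ r.fun) for d, r in fits.items()}
        d_best = min(sse, key=sse.get)
        res = fits[d_best]
        names = list(self.param_names)
        n_stacked = 2 * len(self.obs)
        bse, cis = _linearized_ci(res, names, n_stacked)
        jmax, vc = self.predict(*res.x, d=d_best)
        rmse_j = float(np.sqrt(np.mean((jmax - self._yj) ** 2)))
        rmse_v = float(np.sqrt(np.mean((vc - self._yv) ** 2)))
        var_j = 1.0 - np.sum((jmax - self._yj) ** 2) / np.sum(
            (self._yj - self._yj.mean()) ** 2)
        var_v = 1.0 - np.sum((vc - self._yv) ** 2) / np.sum(
            (self._yv - self._yv.mean()) ** 2)
        params = dict(zip(names, map(float, res.x)))
        return FitResult(
            params=params, bse=bse, conf_ints=cis,
            rmse=float(np.sqrt(np.mean(res.fun**2))),
            n=len(self.obs), converged=bool(res.success),
            fixed=dict(self.fixed),
            diagnostics={
                "d_selected": d_best,
                "sse_by_d": sse,
                "rmse_jmax": rmse_j,
                "rmse_vcmax": rmse_v,
                "var_explained_jmax": float(var_j),
                "var_explained_vcmax": float(var_v),
                "lower_clamp_fraction": self.clamp_fraction(
                    params["p_i1"], params["p_j0"], params["p_j1"], d_best
                ),
            },
        )


def fit_canopy_acclimation(obs, histories, fixed=None, weights=(1.0, 1.0),
                           **fit_kwargs) -> FitResult:
    return CanopyAcclimationModel(obs, histories, fixed, weights).fit(**fit_kwargs)
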