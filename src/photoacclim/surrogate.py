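"""Trait surrogate: regression from bulk leaf traits to optical parameters.

Running the full optics chain (spectral two-stream solve, inversion,
daylight integration, profile fit) per leaf is exact but slow and needs a
spectrum; at run time the three quantities the downstream model consumes —
the product ``p1*k_a``, the effective extinction ``k`` and the broadband
transmittance ``T`` — are instead predicted from ``(Chl, Car, LMA)`` with
Gaussian process regression trained on a population put through the full
chain once.  ``p1`` alone is poorly constrained by bulk traits; only the
product ``p1*k_a`` is a surrogate target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import constants
from .exceptions import InvalidInputError
from .profile import LeafTraits, leaf_profile_pipeline

__all__ = [
    "SurrogateModel",
    "build_training_table",
    "train_surrogate",
    "predict_optical_params",
]

FEATURES = ["chl", "car", "lma"]
TARGETS = ["p1ka", "k", "T"]
SCHEMA_VERSION = 1


def build_training_table(
    population: pd.DataFrame,
    p2: float = constants.P2_DEFAULT,
    percentile_filter: float = 5.0,
    seed: int = 0,
    jitter_sd: float = 0.0,
    grid=None,
    coefficient_table=None,
    training_sources: tuple | None = ("synthetic",),
) -> pd.DataFrame:
    """Run the optics/profile chain per leaf and tabulate surrogate targets.

    ``population`` needs columns ``chl, car, lma`` (optionally ``water``,
    used with ``chl`` for the lower-percentile filter that discards leaves
    too depleted to parameterize reliably).  The stretch exponent ``p2`` is
    held fixed for every leaf.  Per-leaf failures are recorded and skipped
    with a warning rather than aborting the table.

    When the population carries a ``source`` column, only rows whose source
    is in ``training_sources`` enter the table (default: the sampled
    population only).  Fixed validation anchors — individual measured leaves
    appended to generated populations — are application targets of the
    surrogate, not training material, and some sit far outside the
    population's trait cloud.  Pass ``training_sources=None`` to keep all.
    """
    if len(population) < 30:
        raise InvalidInputError("population must have >= 30 leaves")
    pop = population.reset_index(drop=True)
    if training_sources is not None and "source" in pop.columns:
        pop = pop[pop["source"].isin(training_sources)].reset_index(drop=True)
    keep = pop["chl"] >= np.percentile(pop["chl"], percentile_filter)
    if "water" in pop.columns:
        keep &= pop["water"] >= np.percentile(pop["water"], percentile_filter)
    pop = pop[keep].reset_index(drop=True)

    rows = []
    for idx, row in pop.iterrows():
        traits = LeafTraits(chl=row["chl"], car=row["car"], lma=row["lma"])
        try:
            out = leaf_profile_pipeline(
                traits, fix_p2=p2, seed=seed + idx, jitter_sd=jitter_sd,
                grid=grid, coefficient_table=coefficient_table,
            )
        except Exception as exc:
            warnings.warn(
                f"leaf {idx} (chl={row['chl']:.1f}) failed and was skipped: "
                f"{exc}", stacklevel=2,
            )
            continue
        rows.append(
            {"chl": traits.chl, "car": traits.car, "lma": traits.lma,
             "p1ka": out["p1ka"], "k": out["k"], "p2_used": out["p2"],
             "T": out["T"], "rmse": out["rmse"]}
        )
    return pd.DataFrame(rows)


@dataclass
class SurrogateModel:
    """Per-target Gaussian-process regressors with training metadata."""

    models: dict = field(default_factory=dict)
    trait_ranges: dict = field(default_factory=dict)
    cv_r2: dict = field(default_factory=dict)
    n_train: int = 0
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    @property
    def trained(self) -> bool:
        return bool(self.models)

    def predict(self, traits, warn_extrapolation: bool = True) -> dict:
        """Predict ``(p1ka, k, T)`` for one LeafTraits or a trait DataFrame.

        Returns a dict of arrays (or floats for a single leaf) plus an
        ``extrapolated`` flag for probes outside the training trait ranges.
        """
        if not self.trained:
            raise InvalidInputError("surrogate model has not been trained")
        if isinstance(traits, LeafTraits):
            X = np.array([[traits.chl, traits.car, traits.lma]])
            single = True
        else:
            X = np.asarray(traits[FEATURES], dtype=float)
            single = False
        outside = np.zeros(X.shape[0], dtype=bool)
        for j, name in enumerate(FEATURES):
            lo, hi = self.trait_ranges[name]
            outside |= (X[:, j] < lo) | (X[:, j] > hi)
        if warn_extrapolation and outside.any():
            warnings.warn(
                f"{int(outside.sum())} probe(s) outside training trait "
                "ranges; predictions are extrapolations", stacklevel=2,
            )
        out = {t: self.models[t].predict(X) for t in TARGETS}
        out["extrapolated"] = outside
        if single:
            out = {k: (float(v[0]) if k != "extrapolated" else bool(v[0]))
                   for k, v in out.items()}
        return out

    def save(self, path) -> None:
        joblib.dump(
            {"schema_version": self.schema_version, "models": self.models,
             "trait_ranges": self.trait_ranges, "cv_r2": self.cv_r2,
             "n_train": self.n_train, "seed": self.seed},
            path,
        )

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        blob = joblib.load(path)
        if blob.get("schema_version") != SCHEMA_VERSION:
            raise InvalidInputError(
                f"unsupported surrogate schema: {blob.get('schema_version')}"
            )
        return cls(
            models=blob["models"], trait_ranges=blob["trait_ranges"],
            cv_r2=blob["cv_r2"], n_train=blob["n_train"], seed=blob["seed"],
        )


def _make_gp(seed: int) -> Pipeline:
    kernel = ConstantKernel(1.0, (1e-3, 1e4)) * RBF(
        length_scale=[1.0, 1.0, 1.0], length_scale_bounds=(1e-2, 1e4)
    ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-12, 1e1))
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("gp", GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=seed,
                n_restarts_optimizer=1,
            )),
        ]
    )


def train_surrogate(table: pd.DataFrame, seed: int = 0, cv_folds: int = 5
                    ) -> SurrogateModel:
    """Train one GP per target (``p1ka``, ``k``, ``T``) on a training table.

    Features are standardized; held-out R-squared per target comes from
    k-fold cross-validation before the final fit on all rows.  Deterministic
    given the seed.
    """
    if len(table) < 30:
        raise InvalidInputError("training table must have >= 30 rows")
    X = table[FEATURES].to_numpy(float)
    model = SurrogateModel(seed=seed, n_train=len(table))
    model.trait_ranges = {
        name: (float(table[name].min()), float(table[name].max()))
        for name in FEATURES
    }
    for target in TARGETS:
        y = table[target].to_numpy(float)
        if float(np.std(y)) < 1e-14:
            raise InvalidInputError(
                f"target {target!r} is constant; cannot train a regressor"
            )
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        press, sstot = 0.0, float(np.sum((y - y.mean()) ** 2))
        for train_idx, test_idx in kf.split(X):
            gp = _make_gp(seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(X[train_idx], y[train_idx])
            press += float(np.sum((gp.predict(X[test_idx]) - y[test_idx]) ** 2))
        model.cv_r2[target] = 1.0 - press / sstot
        gp = _make_gp(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(X, y)
        model.models[target] = gp
    return model


def predict_optical_params(traits, model: SurrogateModel) -> dict:
    """Predict ``(p1ka, k, T)`` from bulk traits (functional wrapper)."""
    return model.predict(traits)
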