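"""CSV readers/writers and schema validation for the documented formats.

Formats (all plain CSV with headers):

* traits:       ``chl,car,lma`` (optionally ``chl2car,water,source``)
* coefficients: ``wavelength_nm,a_chl,a_car,a_dm,n_refr``
* history:      ``timestamp,i0_ppfd,lai_above,t_air_c`` (optionally
                ``leaf_id`` for multi-leaf files)
* profiles:     ``c_ug_cm2,I_total``
* leaf observations: ``leaf_id,date,layer,z_rel,length_cm,width_cm,
                r713,r709,r703,r699,an,rd,ci``
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .acclimation import LightHistory
from .canopy import (
    RemissionReadings,
    chl_from_remission,
    jleaf_from_gas_exchange,
    lai_above,
    leaf_area,
)
from .exceptions import InvalidInputError

__all__ = [
    "read_traits_csv",
    "read_coefficient_table",
    "read_history_csv",
    "read_profile_csv",
    "read_leaf_observations",
    "derive_leaf_table",
]


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise InvalidInputError(
            f"{what} is missing required columns: {sorted(missing)}"
        )


def read_traits_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "car" not in df.columns and "chl2car" in df.columns:
        df = df.assign(car=df["chl"] / df["chl2car"])
    _require(df, ["chl", "car", "lma"], "traits table")
    bad = df[(df[["chl", "car", "lma"]] <= 0).any(axis=1)]
    if not bad.empty:
        raise InvalidInputError(
            f"traits must be positive; offending rows: {bad.index.tolist()}"
        )
    return df


def read_coefficient_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["wavelength_nm", "a_chl", "a_car", "a_dm", "n_refr"],
             "spectral coefficient table")
    return df.sort_values("wavelength_nm").reset_index(drop=True)


def read_history_csv(path) -> LightHistory | dict:
    """Read an hourly light/temperature history.

    With a ``leaf_id`` column a dict of per-leaf histories is returned.
    """
    df = pd.read_csv(path)
    _require(df, ["timestamp", "i0_ppfd", "lai_above", "t_air_c"],
             "light history")
    if "leaf_id" in df.columns:
        return {
            leaf: LightHistory(sub.drop(columns="leaf_id"))
            for leaf, sub in df.groupby("leaf_id")
        }
    return LightHistory(df)


def read_profile_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    _require(df, ["c_ug_cm2", "I_total"], "light profile")
    return df["c_ug_cm2"].to_numpy(float), df["I_total"].to_numpy(float)


def read_leaf_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(
        df,
        ["leaf_id", "date", "layer", "z_rel", "length_cm", "width_cm",
         "r713", "r709", "r703", "r699", "an", "rd", "ci"],
        "leaf observation table",
    )
    return df


def derive_leaf_table(obs: pd.DataFrame, s_p: float | None = None
                      ) -> pd.DataFrame:
    """Derive per-leaf quantities from a raw canopy observation table.

    Adds single-leaf area (from length and width), chlorophyll content
    (from the four-band remission calibration), overlying leaf-area index
    (per date, layers ordered top to bottom, layer 1 at the top) and the
    whole-leaf electron transport rate from gas exchange.
    """
    from . import constants

    s_p = s_p if s_p is not None else constants.S_P_DEFAULT
    out = obs.copy()
    out["s_l_cm2"] = [
        leaf_area(r.length_cm, r.width_cm) for r in obs.itertuples()
    ]
    out["chl"] = [
        chl_from_remission(
            RemissionReadings(r.r713, r.r709, r.r703, r.r699)
        )
        for r in obs.itertuples()
    ]
    out["jleaf"] = [
        jleaf_from_gas_exchange(r.an, r.rd, r.ci) for r in obs.itertuples()
    ]
    lai = np.full(len(out), np.nan)
    for _, idx in out.groupby("date").groups.items():
        sub = out.loc[idx].sort_values("layer")  # layer 1 = top
        areas = sub["s_l_cm2"].to_numpy(float)
        for pos, row_idx in enumerate(sub.index):
            lai[out.index.get_loc(row_idx)] = lai_above(
                areas[: pos + 1], s_p
            )
    out["lai_t"] = lai
    return out
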