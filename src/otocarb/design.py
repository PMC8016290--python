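"""Covariate construction shared by the simulators and the model fitters.

All covariates are derived from a panel's rows plus the panel's stored
centering constants, so that data simulated from a coefficient vector can be
re-fit with the exact same design.  Base columns:

``const``
    intercept (all ones)
``stock``
    indicator of the non-reference stock (second stock in sorted order,
    i.e. NEA when stocks are {ICE, NEA}; ICE is the reference level)
``sex_m``, ``sex_unknown``
    treatment dummies, female reference
``tl_z``
    total length, centered and scaled by the between-fish SD
``log_age_c``
    natural log of increment age, mean-centered
``age8``
    indicator of the 'old' milled increment level (age >= cut, default 5,
    so ages {7, 8} fall in the level whose reference is age 3)
``sz``
    spawning-zone indicator
``anomt``
    stock-specific temperature anomaly of the formation year
``year_c``
    formation year, mean-centered

Interaction columns are products of base columns and are named with ':'
(e.g. ``log_age_c:stock``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import Centering
from .params import ConfigurationError

REFERENCE_STOCK = "ICE"


def anomaly_lookup(env: pd.DataFrame) -> dict[tuple[str, int], float]:
    return {
        (str(s), int(y)): float(a)
        for s, y, a in zip(env["stock"], env["year"], env["anom_t"])
    }


def base_columns(
    rows: pd.DataFrame,
    centering: Centering,
    env: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Evaluate all base covariate columns for the given panel rows."""
    n = len(rows)
    stocks = sorted(rows["stock"].unique())
    nonref = [s for s in stocks if s != REFERENCE_STOCK]
    if len(nonref) > 1:
        raise ConfigurationError(
            f"more than two stocks present: {stocks}; the design supports "
            "one reference and one alternative level"
        )
    alt = nonref[0] if nonref else None

    cols = {
        "const": np.ones(n),
        "stock": (rows["stock"] == alt).to_numpy(float) if alt else np.zeros(n),
        "sex_m": (rows["sex"] == "M").to_numpy(float),
        "sex_unknown": (rows["sex"] == "UNKNOWN").to_numpy(float),
        "tl_z": (rows["tl_cm"].to_numpy(float) - centering.tl_mean) / centering.tl_sd,
        "log_age_c": np.log(rows["age"].to_numpy(float)) - centering.log_age_mean,
        "age8": (rows["age"].to_numpy(float) >= centering.age_factor_cut).astype(float),
        "sz": rows["spawning_zone"].to_numpy(float),
        "year_c": rows["year"].to_numpy(float) - centering.year_mean,
    }
    if env is not None:
        lut = anomaly_lookup(env)
        keys = list(zip(rows["stock"].astype(str), rows["year"].astype(int)))
        missing = sorted({k for k in keys if k not in lut})
        if missing:
            raise ConfigurationError(
                f"no temperature anomaly for stock-years {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        cols["anomt"] = np.array([lut[k] for k in keys])
    return pd.DataFrame(cols, index=rows.index)


def column(name: str, base: pd.DataFrame) -> np.ndarray:
    """Resolve a (possibly interaction) column name to its values."""
    if name == "intercept":
        name = "const"
    parts = name.split(":")
    try:
        out = base[parts[0]].to_numpy(float).copy()
        for part in parts[1:]:
            out *= base[part].to_numpy(float)
    except KeyError as exc:
        raise ConfigurationError(f"unknown design column {name!r}") from exc
    return out


def linear_predictor(
    coefficients: dict[str, float], base: pd.DataFrame
) -> np.ndarray:
    eta = np.zeros(len(base))
    for name, beta in coefficients.items():
        eta += beta * column(name, base)
    return eta
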