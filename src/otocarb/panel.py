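"""Long-format otolith panel: one row per annual increment per fish.

The panel carries both fish-level covariates (repeated on every row) and
increment-level measurements.  Centering constants for the model covariates
are derived once from the panel itself so that simulation and fitting share
the same reference values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ConfigurationError

#: canonical column order of the serialized panel
COLUMNS = [
    "fish_id",
    "stock",
    "sex",
    "tl_cm",
    "age_at_capture",
    "capture_year",
    "age",
    "year",
    "width_um",
    "spawning_zone",
    "d13c_permil",
    "milled",
    "excluded",
]

_BOOL_COLUMNS = ("spawning_zone", "milled", "excluded")


class PanelValidationError(ValueError):
    """Schema violation in a panel file, with offending row numbers."""


@dataclass
class Centering:
    """Covariate reference values shared between simulation and fitting."""

    log_age_mean: float
    tl_mean: float
    tl_sd: float
    year_mean: float
    age_factor_cut: float = 5.0  # increments at age >= cut are the 'old' level

    def as_dict(self) -> dict[str, float]:
        return {
            "log_age_mean": self.log_age_mean,
            "tl_mean": self.tl_mean,
            "tl_sd": self.tl_sd,
            "year_mean": self.year_mean,
            "age_factor_cut": self.age_factor_cut,
        }


@dataclass
class OtolithPanel:
    data: pd.DataFrame
    centering: Centering = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.centering is None:
            self.centering = compute_centering(self.data)

    # -- convenience views -------------------------------------------------
    @property
    def analysis(self) -> pd.DataFrame:
        """Rows retained for modelling (first/last increments dropped)."""
        return self.data.loc[~self.data["excluded"]]

    @property
    def milled(self) -> pd.DataFrame:
        """Analysis rows with an allocated isotope slot."""
        d = self.data
        return d.loc[d["milled"] & ~d["excluded"]]

    @property
    def fish(self) -> pd.DataFrame:
        cols = ["fish_id", "stock", "sex", "tl_cm", "age_at_capture",
                "capture_year"]
        return self.data[cols].drop_duplicates("fish_id").reset_index(drop=True)

    def stock_year_key(self, frame: pd.DataFrame | None = None) -> pd.Series:
        d = self.data if frame is None else frame
        return d["stock"].astype(str) + ":" + d["year"].astype(int).astype(str)

    def copy(self) -> "OtolithPanel":
        return OtolithPanel(self.data.copy(), self.centering)


def compute_centering(data: pd.DataFrame) -> Centering:
    keep = ~data["excluded"]
    milled = keep & data["milled"]
    fish = data.loc[keep, ["fish_id", "tl_cm"]].drop_duplicates("fish_id")
    tl_sd = float(fish["tl_cm"].std(ddof=1))
    if not np.isfinite(tl_sd) or tl_sd == 0:
        tl_sd = 1.0
    year_rows = milled if milled.any() else keep
    return Centering(
        log_age_mean=float(np.log(data.loc[keep, "age"]).mean()),
        tl_mean=float(fish["tl_cm"].mean()),
        tl_sd=tl_sd,
        year_mean=float(data.loc[year_rows, "year"].mean()),
    )


def validate_panel(data: pd.DataFrame) -> None:
    missing = [c for c in COLUMNS if c not in data.columns]
    if missing:
        raise PanelValidationError(f"missing columns: {missing}")
    errors: list[str] = []

    bad_width = data.index[data["width_um"].notna() & (data["width_um"] <= 0)]
    for idx in bad_width[:5]:
        errors.append(f"row {idx}: non-positive width_um")

    dup = data.duplicated(subset=["fish_id", "age"], keep=False)
    if dup.any():
        rows = list(data.index[dup][:5])
        errors.append(f"duplicate (fish_id, age) at rows {rows}")

    implied = data["capture_year"] - (data["age_at_capture"] - data["age"])
    bad_year = data.index[implied != data["year"]]
    for idx in bad_year[:5]:
        errors.append(f"row {idx}: year inconsistent with capture_year/age")

    bad_age = data.index[(data["age"] < 1) | (data["age"] > data["age_at_capture"])]
    for idx in bad_age[:5]:
        errors.append(f"row {idx}: age outside 1..age_at_capture")

    if errors:
        raise PanelValidationError("; ".join(errors))


def write_panel(panel: OtolithPanel, path) -> None:
    """CSV dialect: UTF-8, header, '.' decimal, empty field = missing."""
    out = panel.data[COLUMNS].copy()
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False, na_rep="")


def read_panel(path) -> OtolithPanel:
    data = pd.read_csv(
        path,
        dtype={"fish_id": str, "stock": str, "sex": str},
        keep_default_na=True,
    )
    for col in _BOOL_COLUMNS:
        if col in data.columns:
            data[col] = data[col].astype(bool)
    for col in ("age", "age_at_capture", "capture_year", "year"):
        if col in data.columns:
            data[col] = data[col].astype(int)
    validate_panel(data)
    return OtolithPanel(data.reset_index(drop=True))


def read_environment(path) -> pd.DataFrame:
    env = pd.read_csv(path, dtype={"stock": str})
    required = {"stock", "year", "temp_c"}
    if not required.issubset(env.columns):
        raise ConfigurationError(
            f"environment file must contain columns {sorted(required)}"
        )
    if "anom_t" not in env.columns:
        env["anom_t"] = env["temp_c"] - env.groupby("stock")["temp_c"].transform("mean")
    return env


def write_environment(env: pd.DataFrame, path) -> None:
    env.to_csv(path, index=False)
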