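"""Configuration dataclasses for cohort simulation and mixing-model sources."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

STOCKS = ("ICE", "NEA")
SEXES = ("F", "M", "UNKNOWN")


class ConfigurationError(ValueError):
    """Raised when generation or fitting parameters are invalid."""


@dataclass
class TraitModel:
    """Fixed coefficients and variance components for one simulated trait.

    Coefficient keys follow the design-term vocabulary used by the fitting
    module (see :mod:`otocarb.lmm`).  Variances are on the (possibly
    log-transformed) response scale.
    """

    coefficients: dict[str, float]
    sigma2_resid: float
    tau_fish: float
    tau_stockyear: float

    def __post_init__(self) -> None:
        for name, value in (
            ("sigma2_resid", self.sigma2_resid),
            ("tau_fish", self.tau_fish),
            ("tau_stockyear", self.tau_stockyear),
        ):
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")


def _default_width_model() -> TraitModel:
    # log-um scale; reference level is the ICE stock
    return TraitModel(
        coefficients={
            "intercept": 5.146,
            "log_age_c": -0.649,
            "log_age_c:stock": 0.133,
            "tl_z": 0.301,
            "stock": 0.041,
            "anomt": 0.020,
        },
        sigma2_resid=0.058,
        tau_fish=0.005,
        tau_stockyear=0.001,
    )


def _default_d13c_model() -> TraitModel:
    # permil VPDB; age enters as a two-level factor (old vs young increment)
    return TraitModel(
        coefficients={
            "intercept": -1.563,
            "age8": 0.036,
            "age8:stock": 0.071,
            "year_c": -0.007,
            "year_c:stock": 0.004,
            "tl_z": -0.203,
            "stock": -0.404,
        },
        sigma2_resid=0.144,
        tau_fish=0.128,
        tau_stockyear=0.034,
    )


@dataclass
class GenerativeParams:
    """Full generative configuration for a synthetic otolith cohort."""

    n_fish: dict[str, int] = field(
        default_factory=lambda: {"ICE": 213, "NEA": 223}
    )
    capture_span: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"ICE": (1929, 2015), "NEA": (1933, 2015)}
    )
    fish_per_year: int = 3
    age_at_capture_choices: tuple[int, ...] = (10, 11)
    milled_ages: tuple[int, ...] = (3, 8)
    rare_milled_ages: tuple[int, ...] = (2, 7)
    rare_milled_frac: float = 0.04
    single_measurement_frac: float = 36.0 / 436.0
    tl_mean: float = 95.0
    tl_sd: float = 10.0
    sex_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)
    sz_prob_old: float = 0.8   # increments at age >= sz_age_onset
    sz_prob_young: float = 0.05
    sz_age_onset: int = 7
    width_model: TraitModel = field(default_factory=_default_width_model)
    d13c_model: TraitModel = field(default_factory=_default_d13c_model)
    # temperature generator (AR(1) around a linear trend, per stock)
    temp_base: dict[str, float] = field(
        default_factory=lambda: {"ICE": 6.0, "NEA": 4.0}
    )
    temp_trend: float = 0.005
    temp_ar1: float = 0.6
    temp_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fish_per_year <= 0:
            raise ConfigurationError("fish_per_year must be positive")
        for stock, n in self.n_fish.items():
            if n <= 0:
                raise ConfigurationError(f"n_fish[{stock}] must be positive")
        for stock, (lo, hi) in self.capture_span.items():
            if hi < lo:
                raise ConfigurationError(
                    f"empty capture span for {stock}: ({lo}, {hi})"
                )
        if not self.milled_ages:
            raise ConfigurationError("milled_ages must be non-empty")
        if any(a < 1 for a in self.age_at_capture_choices):
            raise ConfigurationError("ages at capture must be >= 1")

    @property
    def stocks(self) -> tuple[str, ...]:
        return tuple(self.n_fish)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenerativeParams":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        for key in ("width_model", "d13c_model"):
            if key in doc and isinstance(doc[key], Mapping):
                doc[key] = TraitModel(**doc[key])
        for key in ("capture_span",):
            if key in doc:
                doc[key] = {k: tuple(v) for k, v in doc[key].items()}
        for key in ("age_at_capture_choices", "milled_ages", "rare_milled_ages",
                    "sex_probs"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def demo_params(seed: int = 0) -> GenerativeParams:
    """Small 20-fish configuration used by the test fixture command."""
    return GenerativeParams(
        n_fish={"ICE": 10, "NEA": 10},
        capture_span={"ICE": (2000, 2009), "NEA": (2000, 2009)},
        fish_per_year=1,
        seed=seed,
    )


@dataclass
class StockSources:
    """Isotopic end members for one stock (permil VPDB)."""

    diet_mean: float
    diet_sd: float
    dic_mean: float
    dic_sd: float

    def __post_init__(self) -> None:
        if self.diet_sd < 0 or self.dic_sd < 0:
            raise ConfigurationError("source SDs must be >= 0")
        if not self.diet_mean < self.dic_mean:
            raise ConfigurationError(
                "diet source must be lighter (more negative) than the DIC "
                f"source; got diet={self.diet_mean}, dic={self.dic_mean}"
            )


@dataclass
class SourceConfig:
    """Per-stock source distributions plus the net fractionation offset."""

    stocks: dict[str, StockSources]
    epsilon: float = 2.7

    def __getitem__(self, stock: str) -> StockSources:
        try:
            return self.stocks[stock]
        except KeyError:
            raise ConfigurationError(f"no sources configured for stock {stock!r}")

    def to_yaml(self, path) -> None:
        doc = {
            "epsilon": self.epsilon,
            "stocks": {k: asdict(v) for k, v in self.stocks.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SourceConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(
            stocks={k: StockSources(**v) for k, v in doc["stocks"].items()},
            epsilon=float(doc.get("epsilon", 2.7)),
        )


def default_sources(stocks=STOCKS, epsilon: float = 2.7) -> SourceConfig:
    """Simulation defaults: a depleted diet end member and near-zero DIC."""
    return SourceConfig(
        stocks={
            s: StockSources(diet_mean=-18.5, diet_sd=0.5, dic_mean=1.0, dic_sd=0.3)
            for s in stocks
        },
        epsilon=epsilon,
    )
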