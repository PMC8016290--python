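"""Synthetic otolith cohorts with the statistical structure of the study design.

Two stocks, a handful of fish caught per sampling year at age 10+, annual
increment widths for every year of life, and carbon-isotope values milled
from two increments per fish.  Traits are simulated from crossed
random-intercept linear models (or from the two-source mass balance), so the
downstream fitting stages can be validated by parameter recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import base_columns, linear_predictor
from .panel import COLUMNS, OtolithPanel, validate_panel
from .params import ConfigurationError, GenerativeParams, SourceConfig, SEXES


def _rng(seed, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed), *stream])


# ---------------------------------------------------------------------------
# cohort skeleton


def _capture_years(params: GenerativeParams, stock: str,
                   rng: np.random.Generator) -> np.ndarray:
    lo, hi = params.capture_span[stock]
    years = np.arange(lo, hi + 1)
    n, per = params.n_fish[stock], params.fish_per_year
    n_full, rem = divmod(n, per)
    if n_full >= len(years):
        # more full groups than years: cycle deterministically
        out = np.resize(np.repeat(years, per), n)
        return np.sort(out)
    chosen = np.sort(rng.choice(years, size=n_full, replace=False))
    out = np.repeat(chosen, per)
    if rem:
        left = np.setdiff1d(years, chosen)
        pool = left if len(left) >= rem else years
        extra = np.sort(rng.choice(pool, size=rem, replace=False))
        out = np.sort(np.concatenate([out, extra]))
    return out


def generate_cohort(params: GenerativeParams) -> OtolithPanel:
    """Build the fish and increment skeleton; trait columns left missing.

    Each fish receives one increment row per age 1..age_at_capture, with
    formation year = capture_year - (age_at_capture - age).  Isotope slots
    (``milled``) are allocated at the configured milled ages only; first and
    last increments are flagged ``excluded``.
    """
    rng = _rng(params.seed, 0)
    fish_frames = []
    for stock in params.stocks:
        cy = _capture_years(params, stock, rng)
        n = len(cy)
        ages = rng.choice(params.age_at_capture_choices, size=n)
        sexes = rng.choice(SEXES, size=n, p=params.sex_probs)
        tl = rng.normal(params.tl_mean, params.tl_sd, size=n).clip(min=20.0)
        rare = rng.random(n) < params.rare_milled_frac
        single = rng.random(n) < params.single_measurement_frac
        drop_first = rng.random(n) < 0.5
        fish_frames.append(pd.DataFrame({
            "fish_id": [f"{stock}{i:04d}" for i in range(n)],
            "stock": stock,
            "sex": sexes,
            "tl_cm": np.round(tl, 1),
            "age_at_capture": ages,
            "capture_year": cy,
            "rare_milled": rare,
            "single_measurement": single,
            "drop_first_milled": drop_first,
        }))
    fish = pd.concat(fish_frames, ignore_index=True)

    rows = []
    for rec in fish.itertuples(index=False):
        milled_ages = (params.rare_milled_ages if rec.rare_milled
                       else params.milled_ages)
        milled_ages = [a for a in milled_ages if a <= rec.age_at_capture]
        if rec.single_measurement and len(milled_ages) > 1:
            milled_ages = (milled_ages[1:] if rec.drop_first_milled
                           else milled_ages[:-1])
        for age in range(1, rec.age_at_capture + 1):
            rows.append((
                rec.fish_id, rec.stock, rec.sex, rec.tl_cm,
                rec.age_at_capture, rec.capture_year, age,
                rec.capture_year - (rec.age_at_capture - age),
                np.nan,  # width_um
                False,   # spawning_zone, drawn below
                np.nan,  # d13c_permil
                age in milled_ages,
                age == 1 or age == rec.age_at_capture,
            ))
    data = pd.DataFrame(rows, columns=COLUMNS)

    old = data["age"] >= params.sz_age_onset
    p_sz = np.where(old, params.sz_prob_old, params.sz_prob_young)
    data["spawning_zone"] = rng.random(len(data)) < p_sz

    validate_panel(data)
    return OtolithPanel(data.reset_index(drop=True))


# ---------------------------------------------------------------------------
# environment


def simulate_temperature(params: GenerativeParams,
                         seed: int | None = None) -> pd.DataFrame:
    """AR(1)-around-trend annual temperature series, one per stock.

    The series starts early enough to cover every increment formation year
    implied by the capture spans.  Anomalies are mean-centered per stock.
    """
    rng = _rng(params.seed if seed is None else seed, 1)
    back = max(params.age_at_capture_choices)
    frames = []
    for stock in params.stocks:
        lo, hi = params.capture_span[stock]
        years = np.arange(lo - back, hi + 1)
        m = len(years)
        innov_sd = params.temp_sd * np.sqrt(max(1.0 - params.temp_ar1 ** 2, 1e-12))
        x = np.empty(m)
        x[0] = rng.normal(0.0, params.temp_sd)
        eps = rng.normal(0.0, innov_sd, size=m)
        for t in range(1, m):
            x[t] = params.temp_ar1 * x[t - 1] + eps[t]
        temp = params.temp_base[stock] + params.temp_trend * (years - years[0]) + x
        frames.append(pd.DataFrame({"stock": stock, "year": years, "temp_c": temp}))
    env = pd.concat(frames, ignore_index=True)
    env["anom_t"] = env["temp_c"] - env.groupby("stock")["temp_c"].transform("mean")
    return env


def constant_temperature(params: GenerativeParams,
                         value: float = 5.0) -> pd.DataFrame:
    """Degenerate environment (all anomalies zero); handy for exact checks."""
    back = max(params.age_at_capture_choices)
    frames = []
    for stock in params.stocks:
        lo, hi = params.capture_span[stock]
        years = np.arange(lo - back, hi + 1)
        frames.append(pd.DataFrame({
            "stock": stock, "year": years,
            "temp_c": np.full(len(years), value), "anom_t": 0.0,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# trait simulation (mixed-model route)


def _random_components(keys: pd.Series, sd: float,
                       rng: np.random.Generator,
                       empirical: bool = False) -> np.ndarray:
    levels, codes = np.unique(keys.to_numpy(), return_inverse=True)
    draws = rng.normal(0.0, sd, size=len(levels))
    if empirical and sd > 0 and len(levels) > 1:
        # moment-match so the realized level effects have mean 0 and SD sd
        draws = (draws - draws.mean()) * (sd / draws.std(ddof=1))
    return draws[codes]


def simulate_widths(panel: OtolithPanel, params: GenerativeParams,
                    env: pd.DataFrame, seed: int | None = None) -> OtolithPanel:
    """Fill ``width_um`` for every increment from the log-scale mixed model."""
    out = panel.copy()
    rng = _rng(params.seed if seed is None else seed, 2)
    model = params.width_model
    base = base_columns(out.data, out.centering, env=env)
    eta = linear_predictor(model.coefficients, base)
    eta += _random_components(out.data["fish_id"], np.sqrt(model.tau_fish), rng)
    eta += _random_components(out.stock_year_key(),
                              np.sqrt(model.tau_stockyear), rng)
    eta += rng.normal(0.0, np.sqrt(model.sigma2_resid), size=len(eta))
    out.data["width_um"] = np.exp(eta)
    return out


def simulate_d13c_lmm(panel: OtolithPanel, params: GenerativeParams,
                      seed: int | None = None) -> OtolithPanel:
    """Fill δ13C at milled increments from the isotope mixed model."""
    out = panel.copy()
    rng = _rng(params.seed if seed is None else seed, 3)
    model = params.d13c_model
    mask = out.data["milled"].to_numpy()
    rows = out.data.loc[mask]
    base = base_columns(rows, out.centering)
    eta = linear_predictor(model.coefficients, base)
    eta += _random_components(rows["fish_id"], np.sqrt(model.tau_fish), rng)
    eta += _random_components(out.stock_year_key(rows),
                              np.sqrt(model.tau_stockyear), rng)
    eta += rng.normal(0.0, np.sqrt(model.sigma2_resid), size=len(eta))
    out.data.loc[mask, "d13c_permil"] = eta
    return out


# ---------------------------------------------------------------------------
# trait simulation (mass-balance route)


def simulate_d13c_mass_balance(
    panel: OtolithPanel,
    sources: SourceConfig,
    cresp_truth: float | dict[str, float],
    sd_fish: float = 0.0,
    sd_year: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    empirical: bool = False,
) -> OtolithPanel:
    """Fill δ13C at milled increments from the two-source mass balance.

    Per record, the respired proportion is
    ``p = expit(logit(truth) + u_fish + w_stockyear)`` and
    ``d13c = p*diet + (1-p)*dic + epsilon + e``.  The generative proportion is
    kept in an in-memory column ``cresp_true`` (not serialized) so inversion
    round trips can be checked exactly.  ``empirical=True`` moment-matches
    the random-effect draws (mean 0, exact SD) for recovery experiments.
    """
    out = panel.copy()
    rng = _rng(seed, 4)
    mask = out.data["milled"].to_numpy()
    rows = out.data.loc[mask]

    stocks = rows["stock"].astype(str)
    if isinstance(cresp_truth, dict):
        truth = stocks.map(cresp_truth).to_numpy(float)
    else:
        truth = np.full(len(rows), float(cresp_truth))
    if np.any((truth <= 0) | (truth >= 1)):
        raise ConfigurationError("cresp_truth must lie strictly in (0, 1)")

    eta = logit(truth)
    eta += _random_components(rows["fish_id"], sd_fish, rng, empirical)
    eta += _random_components(out.stock_year_key(rows), sd_year, rng, empirical)
    p = expit(eta)

    diet = stocks.map({s: v.diet_mean for s, v in sources.stocks.items()})
    dic = stocks.map({s: v.dic_mean for s, v in sources.stocks.items()})
    d13c = (p * diet.to_numpy(float) + (1.0 - p) * dic.to_numpy(float)
            + sources.epsilon + rng.normal(0.0, noise_sd, size=len(p)))

    out.data.loc[mask, "d13c_permil"] = d13c
    out.data["cresp_true"] = np.nan
    out.data.loc[mask, "cresp_true"] = p
    return out
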