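"""Suess correction and hierarchical Bayesian respired-carbon estimation.

The mixing model treats each corrected isotope value as a draw from
``Normal(p*mu_diet + (1-p)*mu_dic + eps, s2_resid + p^2 s2_diet +
(1-p)^2 s2_dic)`` with ``logit(p) = alpha_stock + u_fish + w_year``.  Source
uncertainty enters the likelihood variance analytically, so the sampler is
an adaptive Metropolis-within-Gibbs over (alpha, u, w, SDs) — small enough
to run study-scale chains in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .panel import OtolithPanel
from .params import ConfigurationError, SourceConfig, StockSources


# ---------------------------------------------------------------------------
# Suess correction


def suess_correct(
    panel: OtolithPanel,
    slopes: dict[str, float],
    reference_year: int | None = None,
) -> OtolithPanel:
    """Detrend milled isotope values to a common reference year.

    ``corrected = observed - slope * (year - reference_year)``.  By default
    the reference is the most recent formation year among milled rows, so
    corrected values are present-day equivalents; the choice shifts all
    values (and hence the estimated respired proportion) by a constant.
    """
    out = panel.copy()
    milled = out.data["milled"] & out.data["d13c_permil"].notna()
    rows = out.data.loc[milled]
    present = set(rows["stock"].unique())
    missing = present - set(slopes)
    if missing:
        raise ConfigurationError(f"no Suess slope for stocks {sorted(missing)}")
    if reference_year is None:
        reference_year = int(rows["year"].max())

    slope = rows["stock"].map(slopes).to_numpy(float)
    years = rows["year"].to_numpy(float)
    corrected = rows["d13c_permil"].to_numpy(float) - slope * (years - reference_year)
    out.data["d13c_corrected"] = np.nan
    out.data.loc[milled, "d13c_corrected"] = corrected
    out.data.attrs["suess_reference_year"] = reference_year
    return out


def estimate_dic_from_aou(aou, a: float, b: float) -> np.ndarray:
    """Linear AOU predictor of seawater DIC isotope ratio: a - b * AOU."""
    return a - b * np.asarray(aou, float)


# ---------------------------------------------------------------------------
# algebraic inversion


def cresp_invert(d13c, diet_mean: float, dic_mean: float, epsilon: float):
    """Invert the two-source mass balance for the respired proportion.

    Returns ``(p, out_of_range)``; values outside [0, 1] are flagged, not
    clipped.
    """
    if diet_mean == dic_mean:
        raise ConfigurationError(
            "source means are equal; the mixture is unidentifiable"
        )
    d13c = np.asarray(d13c, float)
    p = (d13c - epsilon - dic_mean) / (diet_mean - dic_mean)
    return p, (p < 0) | (p > 1)


def invert_panel(panel: OtolithPanel, sources: SourceConfig,
                 column: str = "d13c_corrected") -> pd.DataFrame:
    """Per-record algebraic inversion on (corrected) milled values."""
    rows = panel.data.loc[panel.data["milled"]
                          & panel.data[column].notna()]
    parts = []
    for stock, grp in rows.groupby("stock", sort=True):
        src = sources[str(stock)]
        p, oob = cresp_invert(grp[column].to_numpy(float),
                              src.diet_mean, src.dic_mean, sources.epsilon)
        parts.append(pd.DataFrame({
            "fish_id": grp["fish_id"].to_numpy(),
            "stock": stock,
            "year": grp["year"].to_numpy(),
            "cresp": p,
            "out_of_range": oob,
        }, index=grp.index))
    return pd.concat(parts).sort_index()


# ---------------------------------------------------------------------------
# hierarchical Bayesian mixing model


@dataclass(frozen=True)
class MixingConfig:
    iterations: int = 10_000
    burn_in: int = 5_000
    thinning: int = 5
    chains: int = 2
    seed: int = 0
    alpha_prior_sd: float = 10.0
    sd_prior_scale: float = 1.0    # half-normal scale for all SDs
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ConfigurationError("iterations must exceed burn_in")
        if self.thinning < 1 or self.chains < 1:
            raise ConfigurationError("invalid thinning/chains")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class MixingPosterior:
    """Per-stock posterior of the hierarchical mixing model."""

    stock: str
    config: MixingConfig
    alpha: np.ndarray       # (chains, draws) logit-scale global level
    sigma_fish: np.ndarray  # (chains, draws)
    sigma_year: np.ndarray
    sigma_resid: np.ndarray
    w: np.ndarray           # (chains, draws, n_years) year deviations
    years: np.ndarray       # (n_years,) calendar years

    @property
    def cresp_draws(self) -> np.ndarray:
        """Proportion-scale draws of the global respired-carbon level."""
        return expit(self.alpha.ravel())

    @property
    def cresp_mean(self) -> float:
        return float(self.cresp_draws.mean())

    @property
    def cresp_sd(self) -> float:
        return float(self.cresp_draws.std(ddof=1))

    def annual_series(self) -> pd.DataFrame:
        """Posterior mean +/- SD of the year-specific respired proportion."""
        a = self.alpha.reshape(-1, 1)
        w = self.w.reshape(-1, self.w.shape[-1])
        p = expit(a + w)
        return pd.DataFrame({
            "stock": self.stock,
            "year": self.years,
            "cresp_mean": p.mean(axis=0),
            "cresp_sd": p.std(axis=0, ddof=1),
        })

    def rhat(self) -> dict[str, float]:
        return {
            "alpha": split_rhat(self.alpha),
            "sigma_fish": split_rhat(self.sigma_fish),
            "sigma_year": split_rhat(self.sigma_year),
            "sigma_resid": split_rhat(self.sigma_resid),
        }

    def geweke(self) -> dict[str, float]:
        return {
            "alpha": max(abs(geweke_z(c)) for c in self.alpha),
            "sigma_resid": max(abs(geweke_z(c)) for c in self.sigma_resid),
        }

    @property
    def converged(self) -> bool:
        return max(self.rhat().values()) < self.config.rhat_threshold

    def summary(self) -> dict:
        lo, hi = np.percentile(self.cresp_draws, [2.5, 97.5])
        return {
            "stock": self.stock,
            "cresp_mean": self.cresp_mean,
            "cresp_sd": self.cresp_sd,
            "cresp_ci": [float(lo), float(hi)],
            "sigma_fish_mean": float(self.sigma_fish.mean()),
            "sigma_year_mean": float(self.sigma_year.mean()),
            "sigma_resid_mean": float(self.sigma_resid.mean()),
            "rhat": self.rhat(),
            "geweke_max_abs_z": self.geweke(),
            "converged": self.converged,
        }


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor."""
    chains = np.asarray(chains, float)
    c, s = chains.shape
    half = s // 2
    splits = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    m, nn = splits.shape
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    b = nn * means.var(ddof=1)
    var_plus = (nn - 1) / nn * w + b / nn
    return float(np.sqrt(var_plus / w))


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score with ESS-adjusted standard errors."""
    chain = np.asarray(chain, float)
    n = len(chain)
    a = chain[: int(first * n)]
    b = chain[int((1 - last) * n):]

    def se(x):
        from .bivariate import effective_sample_size
        ess = max(effective_sample_size(x), 2.0)
        return np.sqrt(x.var(ddof=1) / ess)

    denom = np.hypot(se(a), se(b))
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def _loglik(d13c, p, src: StockSources, epsilon, sigma_r):
    mean = p * src.diet_mean + (1.0 - p) * src.dic_mean + epsilon
    var = (sigma_r ** 2 + (p * src.diet_sd) ** 2
           + ((1.0 - p) * src.dic_sd) ** 2)
    return -0.5 * (np.log(2 * np.pi * var) + (d13c - mean) ** 2 / var)


def _run_chain(d13c, fish, year, src, epsilon, cfg: MixingConfig,
               rng: np.random.Generator):
    n = len(d13c)
    J = int(fish.max()) + 1
    K = int(year.max()) + 1

    alpha = 0.0
    u = np.zeros(J)
    w = np.zeros(K)
    log_su, log_sw, log_sr = np.log(0.3), np.log(0.15), np.log(0.3)

    sc_alpha, sc_u, sc_w, sc_s = 0.1, 0.3, 0.3, 0.2
    acc = np.zeros(4)
    tries = np.zeros(4)

    n_store = cfg.n_draws
    out_alpha = np.empty(n_store)
    out_su = np.empty(n_store)
    out_sw = np.empty(n_store)
    out_sr = np.empty(n_store)
    out_w = np.empty((n_store, K))
    store = 0

    def ll_all(a, uu, ww, sr):
        p = expit(a + uu[fish] + ww[year])
        return _loglik(d13c, p, src, epsilon, sr)

    ll_cur = ll_all(alpha, u, w, np.exp(log_sr))

    for it in range(cfg.iterations):
        sr = np.exp(log_sr)

        # alpha
        prop = alpha + sc_alpha * rng.standard_normal()
        ll_prop = ll_all(prop, u, w, sr)
        delta = (ll_prop.sum() - ll_cur.sum()
                 - (prop ** 2 - alpha ** 2) / (2 * cfg.alpha_prior_sd ** 2))
        tries[0] += 1
        if np.log(rng.random()) < delta:
            alpha, ll_cur = prop, ll_prop
            acc[0] += 1

        # fish effects (independent per-fish accept/reject)
        su = np.exp(log_su)
        step = sc_u * rng.standard_normal(J)
        u_prop = u + step
        ll_prop = ll_all(alpha, u_prop, w, sr)
        d_rec = np.bincount(fish, weights=ll_prop - ll_cur, minlength=J)
        d_prior = -(u_prop ** 2 - u ** 2) / (2 * su ** 2)
        accept = np.log(rng.random(J)) < d_rec + d_prior
        tries[1] += 1
        if accept.any():
            u = np.where(accept, u_prop, u)
            ll_cur = ll_all(alpha, u, w, sr)
        acc[1] += accept.mean()

        # year effects
        sw = np.exp(log_sw)
        step = sc_w * rng.standard_normal(K)
        w_prop = w + step
        ll_prop = ll_all(alpha, u, w_prop, sr)
        d_rec = np.bincount(year, weights=ll_prop - ll_cur, minlength=K)
        d_prior = -(w_prop ** 2 - w ** 2) / (2 * sw ** 2)
        accept = np.log(rng.random(K)) < d_rec + d_prior
        tries[2] += 1
        if accept.any():
            w = np.where(accept, w_prop, w)
            ll_cur = ll_all(alpha, u, w, sr)
        acc[2] += accept.mean()

        # translation moves: shift alpha against the mean of a random-effect
        # vector (likelihood-invariant, priors decide) — decorrelates alpha
        # from mean(u), mean(w) and speeds up its mixing substantially
        for vec, s_vec, m in ((u, np.exp(log_su), J), (w, np.exp(log_sw), K)):
            shift = (s_vec / np.sqrt(m)) * rng.standard_normal()
            a_new = alpha + shift
            delta = (-(a_new ** 2 - alpha ** 2) / (2 * cfg.alpha_prior_sd ** 2)
                     - (np.sum((vec - shift) ** 2) - np.sum(vec ** 2))
                     / (2 * s_vec ** 2))
            if np.log(rng.random()) < delta:
                alpha = a_new
                vec -= shift

        # scale parameters: log-scale random walks
        def sd_logpost(log_s, ssq, m):
            s = np.exp(log_s)
            # N(0, s^2) likelihood of m deviations + half-normal prior + Jacobian
            return (-m * log_s - ssq / (2 * s ** 2)
                    - s ** 2 / (2 * cfg.sd_prior_scale ** 2) + log_s)

        for which in ("u", "w"):
            if which == "u":
                cur, ssq, m = log_su, float(u @ u), J
            else:
                cur, ssq, m = log_sw, float(w @ w), K
            prop = cur + sc_s * rng.standard_normal()
            if np.log(rng.random()) < sd_logpost(prop, ssq, m) - sd_logpost(cur, ssq, m):
                if which == "u":
                    log_su = prop
                else:
                    log_sw = prop

        # residual SD enters the data likelihood
        prop = log_sr + sc_s * rng.standard_normal()
        ll_prop = ll_all(alpha, u, w, np.exp(prop))
        delta = (ll_prop.sum() - ll_cur.sum()
                 - (np.exp(2 * prop) - np.exp(2 * log_sr)) / (2 * cfg.sd_prior_scale ** 2)
                 + (prop - log_sr))
        tries[3] += 1
        if np.log(rng.random()) < delta:
            log_sr, ll_cur = prop, ll_prop
            acc[3] += 1

        # proposal adaptation during burn-in only
        if it < cfg.burn_in and (it + 1) % 100 == 0:
            rates = acc / np.maximum(tries, 1)
            sc_alpha *= np.exp(rates[0] - 0.44)
            sc_u *= np.exp(rates[1] - 0.44)
            sc_w *= np.exp(rates[2] - 0.44)
            sc_s *= np.exp(rates[3] - 0.44)
            acc[:] = 0
            tries[:] = 0

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
            if store < n_store:
                out_alpha[store] = alpha
                out_su[store] = np.exp(log_su)
                out_sw[store] = np.exp(log_sw)
                out_sr[store] = np.exp(log_sr)
                out_w[store] = w
                store += 1

    return (out_alpha[:store], out_su[:store], out_sw[:store],
            out_sr[:store], out_w[:store])


def fit_mixing(
    panel: OtolithPanel,
    sources: SourceConfig,
    config: MixingConfig | None = None,
    seed: int | None = None,
    column: str = "d13c_corrected",
) -> dict[str, MixingPosterior]:
    """Fit the hierarchical mixing model separately for every stock present.

    Requires Suess-corrected isotope values (use ``column='d13c_permil'`` to
    fit uncorrected data).  Runs ``config.chains`` independent chains per
    stock for Gelman-Rubin diagnostics.
    """
    config = config or MixingConfig()
    seed = config.seed if seed is None else seed
    if column not in panel.data.columns:
        raise ConfigurationError(
            f"panel lacks column {column!r}; run suess_correct first"
        )
    rows = panel.data.loc[panel.data["milled"] & panel.data[column].notna()]
    if rows.empty:
        raise ConfigurationError("no isotope records to fit")

    results: dict[str, MixingPosterior] = {}
    for si, (stock, grp) in enumerate(rows.groupby("stock", sort=True)):
        src = sources[str(stock)]
        d13c = grp[column].to_numpy(float)
        _, fish = np.unique(grp["fish_id"].to_numpy(), return_inverse=True)
        years, year = np.unique(grp["year"].to_numpy(int), return_inverse=True)

        chains = []
        for ci in range(config.chains):
            rng = np.random.default_rng([int(seed), 13, si, ci])
            chains.append(_run_chain(d13c, fish, year, src, sources.epsilon,
                                     config, rng))
        results[str(stock)] = MixingPosterior(
            stock=str(stock),
            config=config,
            alpha=np.stack([c[0] for c in chains]),
            sigma_fish=np.stack([c[1] for c in chains]),
            sigma_year=np.stack([c[2] for c in chains]),
            sigma_resid=np.stack([c[3] for c in chains]),
            w=np.stack([c[4] for c in chains]),
            years=years,
        )
    return results


# ---------------------------------------------------------------------------
# stock comparison


def stock_difference(post_a: MixingPosterior, post_b: MixingPosterior) -> dict:
    """Posterior of ``cresp(b) - cresp(a)`` on the proportion scale."""
    da, db = post_a.cresp_draws, post_b.cresp_draws
    m = min(len(da), len(db))
    delta = db[:m] - da[:m]
    lo, hi = np.percentile(delta, [2.5, 97.5])
    return {
        "mean": float(delta.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "significant": bool(lo > 0 or hi < 0),
    }


def annual_synchrony(series_a: pd.DataFrame,
                     series_b: pd.DataFrame) -> dict:
    """Pearson correlation of posterior-mean annual series on common years."""
    merged = series_a.merge(series_b, on="year", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ConfigurationError(
            f"need >= 3 common years, got {len(merged)}"
        )
    r, p = stats.pearsonr(merged["cresp_mean_a"], merged["cresp_mean_b"])
    return {"r": float(r), "p": float(p), "n_years": int(len(merged))}
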