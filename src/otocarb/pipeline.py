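"""End-to-end orchestration: synthesize -> univariate fits -> covariance
decomposition -> Suess correction -> mixing model -> summary + manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bivariate, lmm, mixing, synthetic
from .panel import (OtolithPanel, read_environment, read_panel,
                    write_environment, write_panel)
from .params import (ConfigurationError, GenerativeParams, SourceConfig,
                     default_sources, demo_params)

log = logging.getLogger(__name__)

#: optimal fixed structures mirroring the univariate trait models
D13C_FIXED = ("stock", "age_factor", "age_factor:stock", "tl",
              "year", "year:stock")
WIDTH_FIXED = ("stock", "log_age", "log_age:stock", "tl", "anomt")


@dataclass
class RunConfig:
    out_dir: str = "otocarb_run"
    seed: int = 0
    scale: str = "demo"                  # 'demo' | 'study'
    panel_path: str | None = None        # load instead of synthesize
    env_path: str | None = None
    sources_path: str | None = None
    covar_mcmc: dict = field(default_factory=dict)
    mixing_mcmc: dict = field(default_factory=dict)
    stages: tuple[str, ...] = ("synth", "fit", "covar", "cresp")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _default_covar_mcmc(scale: str) -> dict:
    if scale == "demo":
        return {"iterations": 1_500, "burn_in": 500, "thinning": 2}
    return {"iterations": 12_000, "burn_in": 2_000, "thinning": 10}


def _default_mixing_mcmc(scale: str) -> dict:
    if scale == "demo":
        return {"iterations": 2_000, "burn_in": 1_000, "thinning": 2,
                "chains": 2}
    return {"iterations": 10_000, "burn_in": 5_000, "thinning": 5,
            "chains": 2}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "scale": config.scale,
                      "stages": {}, "outputs": {}, "inputs": {}}
    t_start = time.time()
    stage = "init"
    try:
        # ---------------- synth / load ----------------
        stage = "synth"
        t0 = time.time()
        if config.panel_path:
            panel = read_panel(config.panel_path)
            env = read_environment(config.env_path) if config.env_path else None
            manifest["inputs"]["panel"] = _sha256(Path(config.panel_path))
        else:
            params = (demo_params(config.seed) if config.scale == "demo"
                      else GenerativeParams(seed=config.seed))
            env = synthetic.simulate_temperature(params)
            panel = synthetic.generate_cohort(params)
            panel = synthetic.simulate_widths(panel, params, env)
            panel = synthetic.simulate_d13c_lmm(panel, params)
            params.to_yaml(out / "params.yaml")
        if env is None:
            raise ConfigurationError("an environment series is required")
        write_panel(panel, out / "panel.csv")
        write_environment(env, out / "environment.csv")
        sources = (SourceConfig.from_yaml(config.sources_path)
                   if config.sources_path
                   else default_sources(sorted(panel.data["stock"].unique())))
        sources.to_yaml(out / "sources.yaml")
        manifest["stages"]["synth"] = {"seconds": time.time() - t0}

        # ---------------- univariate fits ----------------
        fits = {}
        if "fit" in config.stages or "cresp" in config.stages:
            stage = "fit"
            t0 = time.time()
            specs = {
                "d13c": lmm.ModelSpec(response="d13c", fixed=D13C_FIXED),
                "log_width": lmm.ModelSpec(response="log_width",
                                           fixed=WIDTH_FIXED),
            }
            for name, spec in specs.items():
                fit = lmm.fit_lmm(spec, panel, env)
                fits[name] = fit
                _write_fit(fit, out / f"fit_{name}")
            manifest["stages"]["fit"] = {"seconds": time.time() - t0}

        # ---------------- bivariate decomposition ----------------
        if "covar" in config.stages:
            stage = "covar"
            t0 = time.time()
            mcmc = {**_default_covar_mcmc(config.scale), **config.covar_mcmc,
                    "seed": config.seed}
            table = bivariate.attribution_table(panel, env=env, mcmc=mcmc)
            table.to_csv(out / "correlations.csv", index=False)
            manifest["stages"]["covar"] = {"seconds": time.time() - t0}

        # ---------------- Suess correction + mixing model ----------------
        if "cresp" in config.stages:
            stage = "cresp"
            t0 = time.time()
            stocks = sorted(panel.data["stock"].unique())
            slopes = {
                s: lmm.year_trend(fits["d13c"], s)["slope_per_year"]
                for s in stocks
            }
            corrected = mixing.suess_correct(panel, slopes)
            cfg = mixing.MixingConfig(
                **{**_default_mixing_mcmc(config.scale), **config.mixing_mcmc,
                   "seed": config.seed})
            posts = mixing.fit_mixing(corrected, sources, cfg)
            series = pd.concat([p.annual_series() for p in posts.values()])
            series.to_csv(out / "cresp_series.csv", index=False)
            summary = {s: p.summary() for s, p in posts.items()}
            summary["suess_slopes"] = slopes
            summary["suess_reference_year"] = corrected.data.attrs[
                "suess_reference_year"]
            if len(posts) == 2:
                a, b = (posts[s] for s in stocks)
                summary["stock_difference"] = mixing.stock_difference(a, b)
                try:
                    summary["annual_synchrony"] = mixing.annual_synchrony(
                        a.annual_series(), b.annual_series())
                except ConfigurationError as exc:
                    summary["annual_synchrony"] = {"error": str(exc)}
            with open(out / "cresp_summary.json", "w", encoding="utf-8") as fh:
                json.dump(summary, fh, indent=2, default=float)
            manifest["stages"]["cresp"] = {"seconds": time.time() - t0}
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {exc}"
        ) from exc

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    manifest["total_seconds"] = time.time() - t_start
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def _write_fit(fit: lmm.LMMFit, stem: Path) -> None:
    """Coefficient-table CSV plus a JSON bundle of fit statistics."""
    tests = lmm.fixed_effect_tests(fit)
    table = fit.coef.copy()
    for col in ("p", "ci_low", "ci_high"):
        table[col] = tests[col] if col in tests else np.nan
    table.to_csv(f"{stem}.csv")
    r2m, r2c = lmm.r2_nakagawa(fit)
    bundle = {
        "response": fit.spec.response,
        "fixed": list(fit.spec.fixed),
        "random": list(fit.spec.random),
        "method": fit.spec.method,
        "sigma2": fit.sigma2,
        "tau": fit.tau,
        "icc": {t: lmm.icc(fit, t) for t in fit.tau},
        "loglik": fit.loglik,
        "aicc": lmm.aicc(fit),
        "r2_marginal": r2m,
        "r2_conditional": r2c,
        "n_obs": fit.n_obs,
        "n_groups": fit.n_groups,
        "converged": fit.converged,
        "boundary": fit.boundary,
    }
    with open(f"{stem}.json", "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, default=float)
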