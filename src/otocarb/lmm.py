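"""Crossed random-intercept linear mixed models for otolith traits.

The two univariate models (isotope ratio and log increment width) share one
engine: a Gaussian LMM with up to two crossed random-intercept factors,
estimated by profiled (RE)ML.  The profiled deviance is optimized over the
log variance ratios gamma_k = tau_k / sigma^2; for each candidate gamma the
fixed effects are solved by generalized least squares and sigma^2 drops out
in closed form.  All linear algebra is done on q-dimensional cross-products
(q = total number of random levels) via the Woodbury identity, so fits are
fast even for panels with thousands of increments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .design import base_columns
from .panel import OtolithPanel
from .params import ConfigurationError

log = logging.getLogger(__name__)

RANDOM_TERMS = ("fish", "stock_year")

#: fixed-effect term vocabulary -> design columns
TERM_COLUMNS: dict[str, tuple[str, ...]] = {
    "stock": ("stock",),
    "sex": ("sex_m", "sex_unknown"),
    "tl": ("tl_z",),
    "tl:stock": ("tl_z:stock",),
    "age_factor": ("age8",),
    "age_factor:stock": ("age8:stock",),
    "age_factor:sex:stock": ("age8:sex_m:stock", "age8:sex_unknown:stock"),
    "log_age": ("log_age_c",),
    "log_age:stock": ("log_age_c:stock",),
    "sz": ("sz",),
    "anomt": ("anomt",),
    "anomt:stock": ("anomt:stock",),
    "year": ("year_c",),
    "year:stock": ("year_c:stock",),
}

#: main-effect term implied by each interaction component
_COMPONENT_MAIN = {
    "stock": "stock", "sex": "sex", "tl": "tl", "age_factor": "age_factor",
    "log_age": "log_age", "anomt": "anomt", "year": "year", "sz": "sz",
}


class SingularDesignError(ValueError):
    """Fixed-effect design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model structure for one univariate trait model."""

    response: str                      # 'd13c' | 'log_width'
    fixed: tuple[str, ...] = ()        # term names, intercept implicit
    random: tuple[str, ...] = ("fish", "stock_year")
    method: str = "reml"               # 'reml' | 'ml'

    def __post_init__(self) -> None:
        if self.response not in ("d13c", "log_width"):
            raise ConfigurationError(f"unknown response {self.response!r}")
        if self.method not in ("reml", "ml"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        for term in self.fixed:
            if term not in TERM_COLUMNS:
                raise ConfigurationError(f"unknown fixed term {term!r}")
            for part in term.split(":"):
                main = _COMPONENT_MAIN[part]
                if main != term and main not in self.fixed:
                    raise ConfigurationError(
                        f"interaction {term!r} requires main effect {main!r}"
                    )
        for term in self.random:
            if term not in RANDOM_TERMS:
                raise ConfigurationError(f"unknown random term {term!r}")

    @property
    def columns(self) -> tuple[str, ...]:
        out = ["const"]
        for term in self.fixed:
            out.extend(TERM_COLUMNS[term])
        return tuple(out)


@dataclass
class LMMFit:
    spec: ModelSpec
    coef: pd.DataFrame                 # estimate, se per design column
    vcov: np.ndarray
    sigma2: float
    tau: dict[str, float]
    loglik: float
    n_obs: int
    n_groups: dict[str, int]
    converged: bool
    boundary: dict[str, bool]
    var_fixed: float                   # variance of the fixed linear predictor
    _solver: "_Solver" = field(repr=False, default=None)  # type: ignore

    @property
    def n_params(self) -> int:
        """Fixed coefficients + variance components (incl. residual)."""
        return len(self.coef) + len(self.tau) + 1


# ---------------------------------------------------------------------------
# design construction


def build_design(
    spec: ModelSpec, panel: OtolithPanel, env: pd.DataFrame | None = None
):
    """Assemble response, fixed design, and random-factor codes."""
    if spec.response == "d13c":
        rows = panel.milled
        rows = rows.loc[rows["d13c_permil"].notna()]
        y = rows["d13c_permil"].to_numpy(float)
    else:
        rows = panel.analysis
        rows = rows.loc[rows["width_um"].notna()]
        y = np.log(rows["width_um"].to_numpy(float))

    needs_env = any("anomt" in t for t in spec.fixed)
    base = base_columns(rows, panel.centering, env=env if needs_env else None)
    X = np.column_stack([_col(base, c) for c in spec.columns])

    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d rows with missing response/covariates", n_dropped)
        rows, y, X = rows.loc[keep], y[keep], X[keep]

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [spec.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise SingularDesignError(
            f"singular fixed-effect design; collinear columns: {bad}"
        )

    codes: dict[str, np.ndarray] = {}
    for term in spec.random:
        key = (rows["fish_id"] if term == "fish"
               else panel.stock_year_key(rows))
        _, c = np.unique(key.to_numpy(), return_inverse=True)
        codes[term] = c
    return y, X, list(spec.columns), codes


def _col(base: pd.DataFrame, name: str) -> np.ndarray:
    from .design import column
    return column(name, base)


# ---------------------------------------------------------------------------
# profiled (RE)ML engine


class _Solver:
    """Cross-product cache and deviance evaluations for one design."""

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 codes: dict[str, np.ndarray]):
        self.n, self.p = X.shape
        self.terms = list(codes)
        self.sizes = [int(c.max()) + 1 if len(c) else 0 for c in codes.values()]
        self.q = sum(self.sizes)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # stacked random design cross-products
        if self.q:
            Z = np.zeros((self.n, self.q))
            off = 0
            for c, s in zip(codes.values(), self.sizes):
                Z[np.arange(self.n), off + c] = 1.0
                off += s
            self.ZtZ = Z.T @ Z
            self.ZtX = Z.T @ X
            self.Zty = Z.T @ y
        self._block = np.concatenate([
            np.full(s, i) for i, s in enumerate(self.sizes)
        ]) if self.q else np.empty(0, int)

    # -- core reductions ----------------------------------------------------
    def _reduce(self, gamma: np.ndarray):
        """Return (XtViX, XtViy, ytViy, logdetW) for V* = I + Z D Z'."""
        if self.q == 0 or np.all(gamma <= 0):
            return self.XtX, self.Xty, self.yty, 0.0
        s = np.sqrt(gamma[self._block])
        W = np.eye(self.q) + (s[:, None] * self.ZtZ) * s[None, :]
        cw = cho_factor(W, lower=True)
        logdetW = 2.0 * float(np.sum(np.log(np.diag(cw[0]))))
        SX = s[:, None] * self.ZtX
        Sy = s * self.Zty
        WiSX = cho_solve(cw, SX)
        WiSy = cho_solve(cw, Sy)
        XtViX = self.XtX - SX.T @ WiSX
        XtViy = self.Xty - SX.T @ WiSy
        ytViy = self.yty - float(Sy @ WiSy)
        return XtViX, XtViy, ytViy, logdetW

    def gls(self, gamma: np.ndarray):
        XtViX, XtViy, ytViy, logdetW = self._reduce(gamma)
        cx = cho_factor(XtViX, lower=True)
        beta = cho_solve(cx, XtViy)
        rss = max(ytViy - float(XtViy @ beta), 1e-300)
        logdetX = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
        return beta, rss, logdetW, logdetX, XtViX

    def deviance(self, gamma: np.ndarray, method: str) -> float:
        _, rss, logdetW, logdetX, _ = self.gls(gamma)
        n, p = self.n, self.p
        if method == "reml":
            s2 = rss / (n - p)
            return ((n - p) * np.log(2 * np.pi * s2) + logdetW + logdetX
                    + (n - p))
        s2 = rss / n
        return n * np.log(2 * np.pi * s2) + logdetW + n

    def deviance_and_grad(self, gamma: np.ndarray, method: str):
        """Profiled deviance and its gradient w.r.t. the variance ratios.

        Uses the envelope theorem: beta and sigma^2 are at their conditional
        optima, so only the explicit gamma dependence contributes.
        """
        n, p, q = self.n, self.p, self.q
        s = np.sqrt(gamma[self._block])
        W = np.eye(q) + (s[:, None] * self.ZtZ) * s[None, :]
        cw = cho_factor(W, lower=True)
        logdetW = 2.0 * float(np.sum(np.log(np.diag(cw[0]))))
        SZtZ = s[:, None] * self.ZtZ
        SX = s[:, None] * self.ZtX
        Sy = s * self.Zty
        WiSZtZ = cho_solve(cw, SZtZ)
        WiSX = cho_solve(cw, SX)
        WiSy = cho_solve(cw, Sy)
        XtViX = self.XtX - SX.T @ WiSX
        XtViy = self.Xty - SX.T @ WiSy
        ytViy = self.yty - float(Sy @ WiSy)
        cx = cho_factor(XtViX, lower=True)
        beta = cho_solve(cx, XtViy)
        rss = max(ytViy - float(XtViy @ beta), 1e-300)
        logdetX = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))

        # q-dimensional projections of V*^{-1}
        ZVZ_diag = np.diag(self.ZtZ) - np.einsum("ij,ij->j", SZtZ, WiSZtZ)
        ZVX = self.ZtX - SZtZ.T @ WiSX          # (q, p)
        ZVy = self.Zty - SZtZ.T @ WiSy          # (q,)
        zr = ZVy - ZVX @ beta                   # Z' V*^{-1} (y - X beta)

        grad = np.empty(len(gamma))
        for k in range(len(gamma)):
            idx = self._block == k
            t_tr = float(ZVZ_diag[idx].sum())
            Gk = ZVX[idx]                       # (q_k, p)
            t_x = float(np.sum(Gk.T * cho_solve(cx, Gk.T)))
            t_r = float(zr[idx] @ zr[idx])
            if method == "reml":
                grad[k] = t_tr - t_x - (n - p) * t_r / rss
            else:
                grad[k] = t_tr - n * t_r / rss
        if method == "reml":
            s2 = rss / (n - p)
            dev = ((n - p) * np.log(2 * np.pi * s2) + logdetW + logdetX
                   + (n - p))
        else:
            s2 = rss / n
            dev = n * np.log(2 * np.pi * s2) + logdetW + n
        return dev, grad

    def deviance_at(self, sigma2: float, tau: np.ndarray) -> float:
        """Non-profiled REML deviance at explicit variance components."""
        gamma = np.asarray(tau, float) / sigma2
        _, rss, logdetW, logdetX, _ = self.gls(gamma)
        n, p = self.n, self.p
        return ((n - p) * np.log(sigma2) + logdetW + logdetX
                + rss / sigma2 + (n - p) * np.log(2 * np.pi))

    def coef_cov(self, sigma2: float, tau: np.ndarray) -> np.ndarray:
        gamma = np.asarray(tau, float) / sigma2
        XtViX, _, _, _ = self._reduce(gamma)
        return sigma2 * np.linalg.inv(XtViX)


_BOUNDARY_GAMMA = 1e-7


def fit_lmm(
    spec: ModelSpec,
    panel: OtolithPanel,
    env: pd.DataFrame | None = None,
) -> LMMFit:
    """Fit a crossed random-intercept LMM by profiled (RE)ML.

    Variance ratios are optimized on the log scale (non-negativity by
    construction); fits that drive a ratio to the lower bound are reported
    with the component set to zero and a boundary flag.  Non-convergence is
    reported in the fit, not raised.
    """
    y, X, columns, codes = build_design(spec, panel, env)
    for term, c in codes.items():
        if len(np.unique(c)) < 2:
            raise ConfigurationError(
                f"random term {term!r} has fewer than 2 levels"
            )
    solver = _Solver(y, X, codes)
    k = len(codes)

    converged = True
    if k:
        # variance ratios optimized directly under a non-negativity bound;
        # the projected gradient escapes gamma=0 when the optimum is interior
        # (a log parametrization stalls there: its gradient vanishes)
        def objective(g):
            return solver.deviance_and_grad(g, spec.method)
        best = None
        for start in ([1.0] * k, [0.05] * k, [10.0] * k):
            res = optimize.minimize(
                objective, x0=np.asarray(start, float), jac=True,
                method="L-BFGS-B", bounds=[(0.0, 1e6)] * k,
                options={"ftol": 1e-15, "gtol": 1e-9, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            if res.success and np.all(res.x > 0):
                break  # interior optimum found; later starts are fallbacks
        converged = bool(best.success) or np.isfinite(best.fun)
        gamma = np.asarray(best.x, float)
        gamma[gamma < _BOUNDARY_GAMMA] = 0.0
        gamma[gamma < _BOUNDARY_GAMMA] = 0.0
    else:
        gamma = np.zeros(0)

    beta, rss, logdetW, logdetX, XtViX = solver.gls(gamma)
    n, p = solver.n, solver.p
    dof = n - p if spec.method == "reml" else n
    sigma2 = rss / dof
    tau = {t: float(g * sigma2) for t, g in zip(solver.terms, gamma)}
    boundary = {t: bool(g == 0.0) for t, g in zip(solver.terms, gamma)}
    loglik = -0.5 * solver.deviance(gamma, spec.method)

    vcov = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(vcov))
    coef = pd.DataFrame({"estimate": beta, "se": se}, index=columns)
    eta = X @ beta
    var_fixed = float(np.var(eta))  # population variance over fitted data

    return LMMFit(
        spec=spec,
        coef=coef,
        vcov=vcov,
        sigma2=float(sigma2),
        tau=tau,
        loglik=float(loglik),
        n_obs=n,
        n_groups={t: s for t, s in zip(solver.terms, solver.sizes)},
        converged=converged,
        boundary=boundary,
        var_fixed=var_fixed,
        _solver=solver,
    )


# ---------------------------------------------------------------------------
# fit statistics


def aicc(fit: LMMFit) -> float:
    """Small-sample corrected AIC: -2 logLik + 2k + 2k(k+1)/(n-k-1)."""
    k, n = fit.n_params, fit.n_obs
    if n <= k + 1:
        raise ConfigurationError(
            f"AICc undefined: n={n} must exceed k+1={k + 1}"
        )
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def icc(fit: LMMFit, term: str) -> float:
    """Share of total variance at one grouping level."""
    if term not in fit.tau:
        raise ConfigurationError(
            f"unknown random term {term!r}; fit has {sorted(fit.tau)}"
        )
    total = fit.sigma2 + sum(fit.tau.values())
    return fit.tau[term] / total


def icc_from_components(sigma2: float, tau: dict[str, float],
                        term: str) -> float:
    if term not in tau:
        raise ConfigurationError(f"unknown random term {term!r}")
    return tau[term] / (sigma2 + sum(tau.values()))


def r2_nakagawa(fit: LMMFit) -> tuple[float, float]:
    """(marginal, conditional) variance-explained of a Gaussian LMM."""
    vf = fit.var_fixed
    vr = sum(fit.tau.values())
    total = vf + vr + fit.sigma2
    return vf / total, (vf + vr) / total


def year_trend(fit: LMMFit, stock: str) -> dict[str, float]:
    """Stock-specific linear year slope and implied change per century."""
    coef = fit.coef["estimate"]
    if "year_c" not in coef.index:
        slope = 0.0
    else:
        slope = float(coef["year_c"])
        if stock != "ICE" and "year_c:stock" in coef.index:
            slope += float(coef["year_c:stock"])
    return {"slope_per_year": slope, "per_century": 100.0 * slope}


# ---------------------------------------------------------------------------
# fixed-effect tests (Satterthwaite small-sample df)


def _phi_cov(fit: LMMFit) -> np.ndarray | None:
    """Asymptotic covariance of (sigma2, tau...) from the REML Hessian."""
    solver = fit._solver
    terms = solver.terms
    phi = np.array([fit.sigma2] + [fit.tau[t] for t in terms])
    m = len(phi)
    steps = np.maximum(np.abs(phi) * 1e-4, 1e-10)

    def dev(v):
        if v[0] <= 0 or np.any(v[1:] < 0):
            return np.inf
        return solver.deviance_at(v[0], v[1:])

    hess = np.empty((m, m))
    f0 = dev(phi)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = steps[i]
            ej = np.zeros(m); ej[j] = steps[j]
            if i == j:
                fp, fmv = dev(phi + ei), dev(phi - ei)
                if not np.isfinite(fmv):  # boundary: one-sided
                    fmv = f0
                    fp2 = dev(phi + 2 * ei)
                    hess[i, i] = (fp2 - 2 * fp + f0) / steps[i] ** 2
                    continue
                hess[i, i] = (fp - 2 * f0 + fmv) / steps[i] ** 2
            else:
                fpp, fpm = dev(phi + ei + ej), dev(phi + ei - ej)
                fmp, fmm = dev(phi - ei + ej), dev(phi - ei - ej)
                if not np.all(np.isfinite([fpp, fpm, fmp, fmm])):
                    hess[i, j] = hess[j, i] = 0.0
                    continue
                hess[i, j] = hess[j, i] = (
                    (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
                )
    try:
        cov = 2.0 * np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
        return None
    return cov


def fixed_effect_tests(fit: LMMFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per-coefficient t tests with Satterthwaite degrees of freedom.

    df for coefficient j is 2*v^2 / Var(v) with v = Var(beta_j) and Var(v)
    obtained by the delta method over the variance components; falls back to
    the residual df when the variance-parameter Hessian is unusable.
    """
    if not fit.converged:
        raise ConfigurationError("refusing to test a non-converged fit")
    names = [c for c in fit.coef.index if c != "const"]
    if not names:
        return pd.DataFrame(
            columns=["estimate", "se", "df", "t", "p", "ci_low", "ci_high"]
        )

    solver = fit._solver
    terms = solver.terms
    phi = np.array([fit.sigma2] + [fit.tau[t] for t in terms])
    resid_df = fit.n_obs - len(fit.coef)
    cov_phi = _phi_cov(fit) if terms else None

    rows = []
    for name in names:
        j = list(fit.coef.index).index(name)
        est = float(fit.coef["estimate"].iloc[j])
        se = float(fit.coef["se"].iloc[j])
        df = float(resid_df)
        if cov_phi is not None:
            steps = np.maximum(np.abs(phi) * 1e-4, 1e-10)
            grad = np.zeros(len(phi))
            for i in range(len(phi)):
                e = np.zeros(len(phi)); e[i] = steps[i]
                hi = phi + e
                lo = np.maximum(phi - e, 0.0)
                lo[0] = max(lo[0], 1e-12)
                vh = solver.coef_cov(hi[0], hi[1:])[j, j]
                vl = solver.coef_cov(lo[0], lo[1:])[j, j]
                grad[i] = (vh - vl) / (hi[i] - lo[i])
            denom = float(grad @ cov_phi @ grad)
            v = se ** 2
            if denom > 0:
                df = float(np.clip(2.0 * v ** 2 / denom, 1.0, resid_df))
        t = est / se
        pval = 2.0 * stats.t.sf(abs(t), df)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        rows.append((name, est, se, df, t, pval, est - tcrit * se,
                     est + tcrit * se))
    return pd.DataFrame(
        rows,
        columns=["term", "estimate", "se", "df", "t", "p", "ci_low", "ci_high"],
    ).set_index("term")


# ---------------------------------------------------------------------------
# two-phase AICc structure selection


def _pick(table: list[tuple[object, float, int]]):
    """Lowest AICc; ties closer than 0.01 go to the smaller model."""
    best = min(table, key=lambda r: (r[1], r[2]))
    near = [r for r in table if r[1] - best[1] < 0.01]
    return min(near, key=lambda r: r[2])


def select_structure(
    panel: OtolithPanel,
    env: pd.DataFrame | None,
    response: str,
    random_candidates: list[tuple[str, ...]],
    fixed_candidates: list[tuple[str, ...]],
) -> tuple[LMMFit, pd.DataFrame]:
    """Two-phase AICc selection.

    Phase 1 compares random structures under REML with the most complex
    fixed structure; phase 2 compares fixed structures under ML with the
    chosen random structure; the winner is refit with REML.
    """
    if not random_candidates or not fixed_candidates:
        raise ConfigurationError("candidate sets must be non-empty")

    ledger: list[dict] = []
    maximal_fixed = max(
        fixed_candidates,
        key=lambda f: sum(len(TERM_COLUMNS[t]) for t in f),
    )

    phase1 = []
    for rand in random_candidates:
        spec = ModelSpec(response=response, fixed=maximal_fixed,
                         random=rand, method="reml")
        f = fit_lmm(spec, panel, env)
        a = aicc(f)
        phase1.append((rand, a, f.n_params))
        ledger.append({"phase": 1, "random": "+".join(rand) or "(none)",
                       "fixed": "+".join(maximal_fixed), "method": "reml",
                       "aicc": a, "k": f.n_params})
    best_random = _pick(phase1)[0]

    phase2 = []
    for fixed in fixed_candidates:
        spec = ModelSpec(response=response, fixed=fixed,
                         random=best_random, method="ml")
        f = fit_lmm(spec, panel, env)
        a = aicc(f)
        phase2.append((fixed, a, f.n_params))
        ledger.append({"phase": 2, "random": "+".join(best_random),
                       "fixed": "+".join(fixed) or "(intercept)",
                       "method": "ml", "aicc": a, "k": f.n_params})
    best_fixed = _pick(phase2)[0]

    final_spec = ModelSpec(response=response, fixed=best_fixed,
                           random=best_random, method="reml")
    final = fit_lmm(final_spec, panel, env)
    return final, pd.DataFrame(ledger)
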