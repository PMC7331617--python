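"""Regression layer: collinearity screening, GLM/GLMM fits, AICc selection, LRT.

Responses are modelled with the families matched to their support:
Poisson (log link) for standardized visit counts, Gamma (log link) for
strictly positive indices such as H2' and interspecific competition, and
Gaussian (identity) for intraspecific competition.  Patch identity can
enter as a random intercept to absorb pseudoreplication of repeated
patch x month rows.

Fixed-effects fits delegate to statsmodels GLM.  Log-likelihoods are
recomputed at the true maximum: Gaussian at the ML error variance and
Gamma at the profiled ML shape (the GLM mean equations do not involve the
shape, so profiling after the fit is exact).  The Poisson random-intercept
model maximizes the Gauss-Hermite-quadrature marginal likelihood; the
Gaussian one delegates to MixedLM with ML (not REML) estimation so that
likelihoods of models with different fixed effects are comparable.

All-subsets selection (``dredge``) enumerates candidate models under a cap
on the number of predictor variables, keeps interactions only when both
parents are present (marginality), ranks by AICc, and reports the best
model plus alternatives within dAICc <= 2.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "FitResult",
    "SelectionTable",
    "vif_screen",
    "fit_model",
    "aicc",
    "enumerate_candidates",
    "dredge",
    "lrt",
]

log = logging.getLogger(__name__)

FAMILIES = ("poisson", "gamma", "gaussian")

GAMMA_ZERO_EPS = 1e-6


# ---------------------------------------------------------------------------
# collinearity screening
# ---------------------------------------------------------------------------

def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1 / (1 - R^2) from regressing it on the others."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return math.inf
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return math.inf
    return 1.0 / (1.0 - r2)


def vif_screen(
    predictors: pd.DataFrame, threshold: float = 3.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the highest-VIF predictor until all VIFs <= threshold.

    Returns the retained column names and a trace table with one row per
    (step, predictor, VIF) evaluation, flagging the column dropped at each
    step.  Exactly collinear predictors get infinite VIF and fall first.
    """
    cols = list(predictors.columns)
    if len(cols) < 2:
        raise ValueError("vif_screen needs at least two predictors")
    if len(predictors) <= len(cols):
        raise ValueError("need more observations than predictors")
    trace_rows = []
    step = 0
    while len(cols) >= 2:
        X = predictors[cols].to_numpy(dtype=float)
        vifs = {c: _vif_one(X, j) for j, c in enumerate(cols)}
        worst = max(cols, key=lambda c: (vifs[c], c))
        drop = vifs[worst] > threshold
        for c in cols:
            trace_rows.append(
                {"step": step, "predictor": c, "vif": vifs[c],
                 "dropped": drop and c == worst}
            )
        if not drop:
            break
        log.info("vif_screen: dropping %s (VIF=%.3g)", worst, vifs[worst])
        cols.remove(worst)
        step += 1
    return cols, pd.DataFrame(trace_rows)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One candidate regression model.

    ``terms`` hold main effects and ``a:b`` interactions in a patsy-style
    mini-grammar; an interaction is only legal when both parents are also
    terms (marginality).  ``group`` names the random-intercept column, or
    None for a fixed-effects GLM.
    """

    response: str
    family: str
    terms: tuple[str, ...] = ()
    group: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        mains = {t for t in self.terms if ":" not in t}
        for t in self.terms:
            if ":" in t:
                parents = t.split(":")
                missing = [p for p in parents if p not in mains]
                if missing:
                    raise ValueError(
                        f"interaction {t!r} violates marginality; missing parents {missing}"
                    )

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit summary sufficient for AICc ranking and LRTs."""

    spec: ModelSpec
    llf: float
    k: int
    n: int
    params: pd.Series
    bse: pd.Series
    deviance: float | None
    converged: bool
    overdispersion: float | None = None  # Pearson chi2 / df, poisson fits only

    def __post_init__(self) -> None:
        if self.k >= self.n:
            raise ValueError(f"k={self.k} must be < n={self.n}")


# ---------------------------------------------------------------------------
# likelihood helpers
# ---------------------------------------------------------------------------

def _gaussian_ml_llf(resid: np.ndarray) -> float:
    n = len(resid)
    sigma2 = float(np.sum(resid**2)) / n
    if sigma2 <= 0:
        return math.inf
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def _gamma_profile_llf(y: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Profile the Gamma shape at fixed means; return (llf, shape_hat)."""
    n = len(y)
    c = float(np.mean(np.log(y) - np.log(mu) - y / mu))  # <= -1 by Jensen

    def neg_ll(log_a: float) -> float:
        a = math.exp(log_a)
        return -(n * (a * math.log(a) - scipy.special.gammaln(a))
                 + a * n * c - float(np.sum(np.log(y))))

    opt = scipy.optimize.minimize_scalar(neg_ll, bounds=(-10, 15), method="bounded")
    return -float(opt.fun), math.exp(float(opt.x))


def _prepare_gamma_response(data: pd.DataFrame, response: str,
                            policy: str = "epsilon") -> pd.DataFrame:
    """Handle non-positive Gamma responses: nudge by epsilon (default) or drop."""
    y = data[response].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError(f"gamma response {response!r} has negative values")
    if (y == 0).any():
        if policy == "epsilon":
            log.warning("gamma response %r has zeros; adding epsilon=%g",
                        response, GAMMA_ZERO_EPS)
            data = data.copy()
            data[response] = y + GAMMA_ZERO_EPS * (y == 0)
        elif policy == "drop":
            log.warning("gamma response %r has zeros; dropping %d rows",
                        response, int((y == 0).sum()))
            data = data.loc[y > 0].copy()
        else:
            raise ValueError(f"unknown gamma zero policy {policy!r}")
    return data


# ---------------------------------------------------------------------------
# Poisson random-intercept GLMM via Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _poisson_ghq_llf(beta: np.ndarray, log_sigma: float, X: np.ndarray,
                     y: np.ndarray, groups: np.ndarray,
                     nodes: np.ndarray, weights: np.ndarray) -> float:
    """Marginal log-likelihood of y_gi ~ Poisson(exp(x_gi b + u_g)), u_g ~ N(0, s^2)."""
    sigma = math.exp(log_sigma)
    eta = X @ beta
    u = math.sqrt(2.0) * sigma * nodes  # (Q,)
    # per-observation log Poisson at each node: (n, Q)
    eta_q = eta[:, None] + u[None, :]
    logp = y[:, None] * eta_q - np.exp(eta_q) - scipy.special.gammaln(y + 1.0)[:, None]
    total = 0.0
    for g in np.unique(groups):
        lg = logp[groups == g].sum(axis=0)  # (Q,)
        total += scipy.special.logsumexp(lg + np.log(weights)) - 0.5 * math.log(math.pi)
    return float(total)


def _fit_poisson_glmm(spec: ModelSpec, data: pd.DataFrame, n_quad: int = 31) -> FitResult:
    import patsy

    y_dm, X_dm = patsy.dmatrices(spec.formula, data, return_type="dataframe")
    y = y_dm.to_numpy(dtype=float).ravel()
    X = X_dm.to_numpy(dtype=float)
    groups = pd.factorize(data.loc[X_dm.index, spec.group])[0]
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    start_glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    x0 = np.append(start_glm.params, math.log(0.5))

    def neg(theta: np.ndarray) -> float:
        return -_poisson_ghq_llf(theta[:-1], theta[-1], X, y, groups, nodes, weights)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = scipy.optimize.minimize(neg, x0, method="BFGS",
                                      options={"gtol": 1e-6, "maxiter": 500})
        # BFGS can stop on precision loss at an already-converged point
        converged = bool(opt.success) or float(np.abs(opt.jac).max()) < 1e-3
        if not converged:
            polish = scipy.optimize.minimize(neg, opt.x, method="Nelder-Mead",
                                             options={"xatol": 1e-8, "fatol": 1e-8})
            if polish.fun <= opt.fun:
                opt.x, opt.fun = polish.x, polish.fun
                converged = bool(polish.success)
    beta = opt.x[:-1]
    names = list(X_dm.columns) + ["patch_re_sd"]
    params = pd.Series(np.append(beta, math.exp(opt.x[-1])), index=names)
    # asymptotic SEs from the inverse Hessian approximation
    try:
        se = np.sqrt(np.diag(opt.hess_inv))
        se[-1] = se[-1] * math.exp(opt.x[-1])  # delta method for sigma
    except Exception:  # pragma: no cover
        se = np.full(len(names), np.nan)
    return FitResult(
        spec=spec,
        llf=-float(opt.fun),
        k=X.shape[1] + 1,  # random-effect variance counts as one parameter
        n=len(y),
        params=params,
        bse=pd.Series(se, index=names),
        deviance=None,
        converged=converged,
    )


def _fit_gaussian_lmm(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec.formula, data, groups=data[spec.group])
        res = model.fit(reml=False)
    params = res.fe_params.copy()
    params["patch_re_var"] = float(res.cov_re.iloc[0, 0])
    bse = res.bse_fe.copy()
    bse["patch_re_var"] = np.nan
    return FitResult(
        spec=spec,
        llf=float(res.llf),
        k=len(res.fe_params) + 2,  # random-effect variance + residual variance
        n=int(res.nobs),
        params=params,
        bse=bse,
        deviance=None,
        converged=bool(res.converged),
    )


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def fit_model(spec: ModelSpec, data: pd.DataFrame,
              gamma_zero_policy: str = "epsilon") -> FitResult:
    """Fit one model by maximum likelihood.

    Poisson responses must be non-negative integers; Gamma responses
    strictly positive (zeros handled per ``gamma_zero_policy``).  Random
    intercepts are supported for Poisson (Gauss-Hermite marginal
    likelihood) and Gaussian (MixedLM, ML); Gamma mixed models are not.
    """
    data = data.dropna(subset=[spec.response]).copy()
    y = data[spec.response].to_numpy(dtype=float)

    if spec.family == "poisson":
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("poisson response must be non-negative integers")
        if spec.group is not None:
            return _fit_poisson_glmm(spec, data)
        res = smf.glm(spec.formula, data, family=sm.families.Poisson()).fit()
        pearson = float(res.pearson_chi2)
        dof = res.df_resid
        return FitResult(
            spec=spec, llf=float(res.llf), k=len(res.params), n=int(res.nobs),
            params=res.params, bse=res.bse, deviance=float(res.deviance),
            converged=bool(res.converged),
            overdispersion=pearson / dof if dof > 0 else math.nan,
        )

    if spec.family == "gamma":
        if spec.group is not None:
            raise NotImplementedError("gamma random-intercept models are not supported")
        data = _prepare_gamma_response(data, spec.response, gamma_zero_policy)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.glm(spec.formula, data,
                          family=sm.families.Gamma(sm.families.links.Log())).fit()
        yv = data[spec.response].to_numpy(dtype=float)
        llf, _shape = _gamma_profile_llf(yv, np.asarray(res.mu))
        return FitResult(
            spec=spec, llf=llf, k=len(res.params) + 1, n=int(res.nobs),
            params=res.params, bse=res.bse, deviance=float(res.deviance),
            converged=bool(res.converged),
        )

    # gaussian
    if spec.group is not None:
        return _fit_gaussian_lmm(spec, data)
    res = smf.glm(spec.formula, data, family=sm.families.Gaussian()).fit()
    llf = _gaussian_ml_llf(np.asarray(res.resid_response))
    return FitResult(
        spec=spec, llf=llf, k=len(res.params) + 1, n=int(res.nobs),
        params=res.params, bse=res.bse, deviance=float(res.deviance),
        converged=bool(res.converged),
    )


def aicc(fit: FitResult) -> float:
    """Small-sample corrected AIC: -2 llf + 2k + 2k(k+1)/(n-k-1)."""
    n, k = fit.n, fit.k
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * fit.llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# all-subsets selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionTable:
    """Ranked model-selection results (ascending AICc)."""

    table: pd.DataFrame
    fits: tuple[FitResult, ...]

    @property
    def best(self) -> FitResult:
        return self.fits[0]

    @property
    def alternatives(self) -> tuple[FitResult, ...]:
        """Competitive models: dAICc <= 2, excluding the best itself."""
        mask = (self.table["delta_aicc"] <= 2.0) & (self.table.index != 0)
        return tuple(self.fits[i] for i in self.table.index[mask])


def enumerate_candidates(
    predictors: Sequence[str],
    interactions: Sequence[str] = (),
    forced: Sequence[str] = (),
    max_terms: int | None = None,
) -> list[tuple[str, ...]]:
    """All term sets respecting marginality, forced terms, and the predictor cap.

    ``max_terms`` caps the number of non-forced main-effect predictors per
    model (interactions and forced terms are not counted, matching the
    "maximum number of predictor variables" convention of small-sample
    selection).  The null (forced-only) model is always included.
    """
    preds = [p for p in predictors if p not in forced]
    out: list[tuple[str, ...]] = []
    for r in range(len(preds) + 1):
        if max_terms is not None and r > max_terms:
            break
        for combo in itertools.combinations(preds, r):
            mains = tuple(forced) + combo
            eligible = [
                i for i in interactions
                if all(parent in mains for parent in i.split(":"))
            ]
            for ir in range(len(eligible) + 1):
                for icombo in itertools.combinations(eligible, ir):
                    out.append(mains + icombo)
    return out


def dredge(
    data: pd.DataFrame,
    response: str,
    family: str,
    predictors: Sequence[str],
    interactions: Sequence[str] = (),
    forced: Sequence[str] = (),
    max_terms: int | None = None,
    group: str | None = None,
    gamma_zero_policy: str = "epsilon",
) -> SelectionTable:
    """Exhaustive AICc model selection over all legal sub-models.

    Fits every candidate returned by :func:`enumerate_candidates`, ranks
    converged fits by AICc and reports dAICc relative to the best model.
    Non-converged fits are excluded from the ranking (logged).
    """
    specs = [
        ModelSpec(response=response, family=family, terms=terms, group=group)
        for terms in enumerate_candidates(predictors, interactions, forced, max_terms)
    ]
    fits: list[FitResult] = []
    for spec in specs:
        try:
            fit = fit_model(spec, data, gamma_zero_policy=gamma_zero_policy)
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("dredge: %s failed to fit (%s); skipped", spec.formula, exc)
            continue
        if not fit.converged:
            log.warning("dredge: %s did not converge; excluded from ranking", spec.formula)
            continue
        fits.append(fit)
    if not fits:
        raise RuntimeError("dredge: no candidate model converged")
    ranked = sorted(fits, key=lambda f: aicc(f))
    aiccs = [aicc(f) for f in ranked]
    table = pd.DataFrame(
        {
            "terms": [" + ".join(f.spec.terms) or "1" for f in ranked],
            "k": [f.k for f in ranked],
            "llf": [f.llf for f in ranked],
            "aicc": aiccs,
            "delta_aicc": [a - aiccs[0] for a in aiccs],
        }
    )
    return SelectionTable(table=table, fits=tuple(ranked))


def lrt(nested: FitResult, full: FitResult, tol: float = 1e-6) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested model against the full model.

    Returns (chi2, df, p) with chi2 = 2(llf_full - llf_nested) and p from
    the upper chi-square tail.  Identical models give (0, 0, 1).
    """
    if nested.n != full.n:
        raise ValueError(f"models fit to different data (n={nested.n} vs {full.n})")
    chi2 = 2.0 * (full.llf - nested.llf)
    if chi2 < -tol * max(1.0, abs(full.llf)):
        raise ValueError(
            f"full model has lower likelihood than nested ({full.llf} < {nested.llf}); "
            "models are not nested or a fit failed to converge"
        )
    chi2 = max(chi2, 0.0)
    df = full.k - nested.k
    if df < 0:
        raise ValueError(f"full model has fewer parameters than nested (df={df})")
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, float(scipy.stats.chi2.sf(chi2, df))
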