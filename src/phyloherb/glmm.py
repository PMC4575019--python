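"""Random-intercept GLMMs for the per-plant metrics, with LRT and R².

Four response models, one per metric:

====================  ==================  =========================
response              family / link       extras
====================  ==================  =========================
richness              Poisson / log       offset = log total assemblage richness
mean_jaccard          Binomial / logit    prior weights = n comparators
mean_simpson          Binomial / logit    prior weights = n comparators
mean_dprime           Gaussian / identity residual variance estimated
====================  ==================  =========================

Fixed effects are phylogenetic isolation (PI, z-scored by default), plant
origin (PO; native = 1 so positive coefficients mean larger values on
natives) and optionally their interaction; the random effect is an
intercept per assemblage.  The marginal likelihood integrates the random
intercept out by adaptive Gauss-Hermite quadrature centred on the
per-group posterior mode (the Laplace approximation is the one-node
special case; the Gaussian family is handled exactly).  The interaction
term is kept or dropped by a likelihood-ratio test, and fits whose random
intercept explains no variance fall back to a fixed-effects GLM scored by
McFadden's pseudo-R²; mixed fits report Nakagawa-style marginal and
conditional R².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

RESPONSE_FAMILY = {
    "richness": "poisson",
    "mean_jaccard": "binomial",
    "mean_simpson": "binomial",
    "mean_dprime": "gaussian",
}

_GH_NODES = 15
_SINGULAR_VARIANCE_TOL = 1e-8


class FitError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Declarative description of one model."""

    response: str
    family: str = ""
    interaction: bool = True
    offset: str | None = None
    weights: str | None = None
    groups: str = "assemblage_id"
    standardize_pi: bool = True
    alpha: float = 0.05
    #: "lrt" falls back to fixed effects when the random intercept is not
    #: supported by a boundary likelihood-ratio test at ``fallback_alpha``;
    #: "threshold" falls back only when the fitted variance is ~0.
    fallback_rule: str = "lrt"
    fallback_alpha: float = 0.01

    def __post_init__(self) -> None:
        if not self.family:
            if self.response not in RESPONSE_FAMILY:
                raise ValueError(f"cannot infer family for response {self.response!r}")
            self.family = RESPONSE_FAMILY[self.response]
        if self.family not in ("poisson", "binomial", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.response == "richness" and self.offset is None:
            self.offset = "assemblage_richness"
        if self.family == "binomial" and self.weights is None:
            self.weights = "n_native_comparators"


@dataclass
class ModelFit:
    spec: ModelSpec
    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    statistics: np.ndarray
    pvalues: np.ndarray
    stat_label: str  # "z" | "t"
    sigma_u: float
    sigma_resid: float | None
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    fallback_used: bool = False
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    mcfadden: float | None = None
    pi_scale: float = 1.0
    pi_center: float = 0.0
    extra: dict = field(default_factory=dict)

    @property
    def random_variance(self) -> float:
        return self.sigma_u**2

    def coef(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])

    def coef_raw(self, term: str) -> float:
        """Coefficient on the unstandardized PI scale."""
        est = self.coef(term)
        if term in ("PI", "PI:PO") and self.pi_scale != 1.0:
            return est / self.pi_scale
        return est

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "se": self.se,
                "statistic": self.statistics,
                "p": self.pvalues,
            }
        )


@dataclass
class LRTResult:
    chi_squared: float
    df: int
    p_value: float
    keep_interaction: bool


# ---------------------------------------------------------------------------
# design matrix


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str], float, float]:
    """Return (X, y, offset, weights, group_idx, terms, pi_center, pi_scale)."""
    cols = ["phylo_isolation", "origin", spec.response, spec.groups]
    if spec.offset:
        cols.append(spec.offset)
    if spec.weights:
        cols.append(spec.weights)
    df = data[cols].dropna()
    if df.empty:
        raise FitError("no complete rows for model")
    pi = df["phylo_isolation"].to_numpy(dtype=float)
    center, scale = 0.0, 1.0
    if spec.standardize_pi:
        center = float(pi.mean())
        scale = float(pi.std(ddof=0))
        if scale <= 0:
            raise FitError("phylogenetic isolation has zero variance (rank-deficient design)")
        pi = (pi - center) / scale
    po = (df["origin"].to_numpy() == "native").astype(float)
    if po.min() == po.max():
        raise FitError("all plants share one origin (rank-deficient design)")
    columns = [np.ones(len(df)), pi, po]
    terms = ["(Intercept)", "PI", "PO"]
    if spec.interaction:
        columns.append(pi * po)
        terms.append("PI:PO")
    X = np.column_stack(columns)
    y = df[spec.response].to_numpy(dtype=float)
    offset = (
        np.log(df[spec.offset].to_numpy(dtype=float)) if spec.offset else np.zeros(len(df))
    )
    weights = (
        df[spec.weights].to_numpy(dtype=float) if spec.weights else np.ones(len(df))
    )
    if spec.family == "binomial":
        eps = 1e-9
        y = np.clip(y, eps, 1 - eps)
    groups, group_idx = np.unique(df[spec.groups].to_numpy(), return_inverse=True)
    return X, y, offset, weights, group_idx, terms, center, scale


# ---------------------------------------------------------------------------
# family log-likelihoods (per observation) and derivatives in eta


def _ll_terms(family: str, y, eta, w, sigma_e):
    if family == "poisson":
        mu = np.exp(eta)
        return y * eta - mu - special.gammaln(y + 1.0)
    if family == "binomial":
        # w * [y*eta - log(1 + e^eta)]; binomial coefficient constant omitted
        return w * (y * eta - np.logaddexp(0.0, eta))
    mu = eta
    return -0.5 * np.log(2 * np.pi * sigma_e**2) - (y - mu) ** 2 / (2 * sigma_e**2)


def _dll(family: str, y, eta, w, sigma_e):
    if family == "poisson":
        return y - np.exp(eta)
    if family == "binomial":
        return w * (y - special.expit(eta))
    return (y - eta) / sigma_e**2


def _d2ll(family: str, y, eta, w, sigma_e):
    if family == "poisson":
        return -np.exp(eta)
    if family == "binomial":
        mu = special.expit(eta)
        return -w * mu * (1 - mu)
    return -np.ones_like(eta) / sigma_e**2


# ---------------------------------------------------------------------------
# marginal likelihood via adaptive Gauss-Hermite quadrature

_gh_x, _gh_w = np.polynomial.hermite.hermgauss(_GH_NODES)
_gh_logw = np.log(_gh_w)


def _group_matrix(group_idx: np.ndarray, n_groups: int) -> np.ndarray:
    G = np.zeros((len(group_idx), n_groups))
    G[np.arange(len(group_idx)), group_idx] = 1.0
    return G


def _marginal_nll(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    w: np.ndarray,
    group_idx: np.ndarray,
    G: np.ndarray,
    family: str,
    mixed: bool,
    warm_u: dict,
) -> float:
    p = X.shape[1]
    beta = theta[:p]
    k = p
    sigma_u = 0.0
    if mixed:
        sigma_u = float(np.exp(theta[k]))
        k += 1
    sigma_e = float(np.exp(theta[k])) if family == "gaussian" else 1.0
    eta0 = X @ beta + offset
    if not mixed:
        return -float(np.sum(_ll_terms(family, y, eta0, w, sigma_e)))

    n_groups = G.shape[1]
    u = warm_u.get("u")
    if u is None or len(u) != n_groups:
        u = np.zeros(n_groups)
    else:
        u = u.copy()
    inv_var = 1.0 / sigma_u**2
    # Newton iterations for the per-group posterior mode of u
    for _ in range(100):
        eta = eta0 + u[group_idx]
        g1 = np.bincount(group_idx, weights=_dll(family, y, eta, w, sigma_e), minlength=n_groups) - u * inv_var
        g2 = np.bincount(group_idx, weights=_d2ll(family, y, eta, w, sigma_e), minlength=n_groups) - inv_var
        step = g1 / (-g2)
        step = np.clip(step, -4.0, 4.0)
        u = u + step
        if np.max(np.abs(g1 * step)) < 1e-10:
            break
    warm_u["u"] = u
    eta = eta0 + u[group_idx]
    h = -(
        np.bincount(group_idx, weights=_d2ll(family, y, eta, w, sigma_e), minlength=n_groups)
        - inv_var
    )
    h = np.maximum(h, 1e-12)
    scale = np.sqrt(2.0 / h)  # (n_groups,)
    # quadrature nodes: u_kg = u_g + scale_g * x_k
    u_nodes = u[None, :] + scale[None, :] * _gh_x[:, None]  # (K, n_groups)
    eta_nodes = eta0[None, :] + u_nodes[:, group_idx]  # (K, n_obs)
    obs_ll = _ll_terms(family, y[None, :], eta_nodes, w[None, :], sigma_e)
    group_ll = obs_ll @ G  # (K, n_groups)
    joint = (
        group_ll
        - u_nodes**2 * (0.5 * inv_var)
        - 0.5 * np.log(2 * np.pi * sigma_u**2)
        + _gh_logw[:, None]
        + (_gh_x**2)[:, None]
    )
    mx = joint.max(axis=0)
    log_int = mx + np.log(np.sum(np.exp(joint - mx), axis=0)) + np.log(scale)
    total = float(np.sum(log_int))
    if not np.isfinite(total):
        return 1e12
    return -total


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    del f0
    return H


def _fit_theta(objective, theta0, bounds, restarts=3, seed=0):
    best = None
    rng = np.random.default_rng(seed)
    start = np.asarray(theta0, dtype=float)
    for attempt in range(restarts + 1):
        res = optimize.minimize(
            objective, start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
        start = np.asarray(theta0) + rng.normal(scale=0.25, size=len(theta0))
        logger.debug("refit attempt %d after non-convergence", attempt + 1)
    return best


def fit_model(data: pd.DataFrame, spec: ModelSpec, mixed: bool = True) -> ModelFit:
    """Maximum-likelihood fit of the specified model.

    ``mixed=False`` drops the random intercept (plain GLM), used for the
    fallback path and for null models.
    """
    X, y, offset, w, group_idx, terms, center, scale = build_design(data, spec)
    n_groups = int(group_idx.max()) + 1
    if mixed and n_groups < 2:
        raise FitError("mixed model requires at least 2 assemblages")
    G = _group_matrix(group_idx, n_groups)
    p = X.shape[1]
    warm: dict = {}

    def obj(theta):
        return _marginal_nll(theta, X, y, offset, w, group_idx, G, spec.family, mixed, warm)

    # starting values: fixed-effects-only fit first
    theta_fix0 = np.zeros(p + (1 if spec.family == "gaussian" else 0))
    if spec.family == "gaussian":
        theta_fix0[0] = float(np.mean(y))
        theta_fix0[-1] = float(np.log(np.std(y) + 1e-6))
    elif spec.family == "poisson":
        theta_fix0[0] = float(np.log(np.mean(y) + 0.5) - np.mean(offset))
    warm_fix: dict = {}
    res_fix = _fit_theta(
        lambda t: _marginal_nll(t, X, y, offset, w, group_idx, G, spec.family, False, warm_fix),
        theta_fix0,
        bounds=None,
    )
    if not mixed:
        res = res_fix
        sigma_u = 0.0
        sigma_e = float(np.exp(res.x[p])) if spec.family == "gaussian" else None
    else:
        theta0 = list(res_fix.x[:p]) + [np.log(0.3)]
        bounds = [(None, None)] * p + [(-10.0, 5.0)]
        if spec.family == "gaussian":
            theta0.append(res_fix.x[p])
            bounds.append((-12.0, 6.0))
        res = _fit_theta(obj, theta0, bounds=bounds)
        sigma_u = float(np.exp(res.x[p]))
        sigma_e = float(np.exp(res.x[-1])) if spec.family == "gaussian" else None
    beta = res.x[:p]
    loglik = -float(res.fun)

    # Wald SEs from the finite-difference Hessian of the negative loglik
    f = obj if mixed else (
        lambda t: _marginal_nll(t, X, y, offset, w, group_idx, G, spec.family, False, warm_fix)
    )
    H = _numeric_hessian(f, res.x)
    try:
        cov = np.linalg.pinv(H)
        var = np.diag(cov)[:p]
        var = np.where(var > 0, var, np.nan)
        se = np.sqrt(var)
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(p, np.nan)
    stat = beta / se
    if spec.family == "gaussian":
        dof = max(len(y) - p, 1)
        pvals = 2 * stats.t.sf(np.abs(stat), df=dof)
        stat_label = "t"
    else:
        pvals = 2 * stats.norm.sf(np.abs(stat))
        stat_label = "z"
    fit = ModelFit(
        spec=spec,
        terms=terms,
        estimates=beta,
        se=se,
        statistics=stat,
        pvalues=pvals,
        stat_label=stat_label,
        sigma_u=sigma_u,
        sigma_resid=sigma_e,
        loglik=loglik,
        n_obs=len(y),
        n_groups=n_groups,
        converged=bool(res.success),
        fallback_used=not mixed,
        pi_scale=scale,
        pi_center=center,
        extra={"offset_mean": float(np.mean(offset)), "fixed_linpred_var": float(np.var(X @ beta))},
    )
    if mixed:
        r2m, r2c = r2_nakagawa(fit)
        fit.r2_marginal, fit.r2_conditional = r2m, r2c
    return fit


# ---------------------------------------------------------------------------
# likelihood ratio test for the interaction


def lrt_interaction(
    data: pd.DataFrame, spec: ModelSpec, mixed: bool = True
) -> tuple[LRTResult, ModelFit]:
    """Compare models with and without PI x PO; return the chosen fit.

    The interaction is removed when chi² = 2(ll_full - ll_reduced) is not
    significant at ``spec.alpha`` on 1 df.
    """
    import dataclasses as _dc

    full_spec = _dc.replace(spec, interaction=True)
    red_spec = _dc.replace(spec, interaction=False)
    full = fit_model(data, full_spec, mixed=mixed)
    red = fit_model(data, red_spec, mixed=mixed)
    chi2 = 2.0 * (full.loglik - red.loglik)
    if chi2 < -1e-4:
        raise FitError(
            f"full model log-likelihood below reduced ({full.loglik:.6f} < {red.loglik:.6f})"
        )
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=1))
    keep = p < spec.alpha
    result = LRTResult(chi_squared=chi2, df=1, p_value=p, keep_interaction=keep)
    return result, (full if keep else red)


# ---------------------------------------------------------------------------
# fallback to fixed effects and pseudo-R²


def fallback_if_singular(fit: ModelFit, data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Refit without the random intercept when it carries no variance.

    Under rule "threshold" the trigger is variance < 1e-8.  Under the
    default rule "lrt" the trigger is a non-significant boundary
    likelihood-ratio test for the random intercept (p >= fallback_alpha,
    with the 0.5 chi²(0) + 0.5 chi²(1) reference mixture), which also fires
    whenever the variance is ~0.
    """
    import dataclasses as _dc

    spec = _dc.replace(spec, interaction="PI:PO" in fit.terms)
    trigger = fit.random_variance < _SINGULAR_VARIANCE_TOL
    fixed = fit_model(data, spec, mixed=False)
    if not trigger and spec.fallback_rule == "lrt":
        lr = max(2.0 * (fit.loglik - fixed.loglik), 0.0)
        p_re = 0.5 * float(stats.chi2.sf(lr, df=1))
        trigger = p_re >= spec.fallback_alpha
    if not trigger:
        return fit
    null_spec = _dc.replace(spec, interaction=False)
    fixed.mcfadden = mcfadden_pseudo_r2(fixed, data, null_spec)
    fixed.fallback_used = True
    return fixed


def mcfadden_pseudo_r2(fit: ModelFit, data: pd.DataFrame, spec: ModelSpec) -> float:
    """1 - ll_model / ll_null with an intercept(+offset)-only null GLM."""
    X, y, offset, w, group_idx, _, _, _ = build_design(data, spec)
    G = _group_matrix(group_idx, int(group_idx.max()) + 1)
    X0 = X[:, :1]
    theta0 = np.zeros(1 + (1 if spec.family == "gaussian" else 0))
    if spec.family == "gaussian":
        theta0[0] = float(np.mean(y))
        theta0[-1] = float(np.log(np.std(y) + 1e-6))
    warm: dict = {}
    res = _fit_theta(
        lambda t: _marginal_nll(t, X0, y, offset, w, group_idx, G, spec.family, False, warm),
        theta0,
        bounds=None,
    )
    ll_null = -float(res.fun)
    if ll_null == 0:
        return 0.0
    return float(1.0 - fit.loglik / ll_null)


def r2_nakagawa(fit: ModelFit) -> tuple[float, float]:
    """Marginal and conditional R² from the fitted variance partition.

    Distribution-specific variance: Gaussian -> residual variance; logit
    binomial -> π²/3; log Poisson -> ln(1 + 1/λ) with λ evaluated at the
    intercept plus mean offset (lognormal approximation).
    """
    if fit.fallback_used:
        raise ValueError("Nakagawa R² undefined for fixed-effects fits; use McFadden")
    var_f = fit.extra["fixed_linpred_var"]
    var_u = fit.random_variance
    fam = fit.spec.family
    if fam == "gaussian":
        var_d = (fit.sigma_resid or 0.0) ** 2
    elif fam == "binomial":
        var_d = np.pi**2 / 3.0
    else:
        lam = float(np.exp(fit.coef("(Intercept)") + fit.extra.get("offset_mean", 0.0)))
        var_d = float(np.log1p(1.0 / lam))
    denom = var_f + var_u + var_d
    return var_f / denom, (var_f + var_u) / denom


# ---------------------------------------------------------------------------
# one response, end to end


def fit_response(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[LRTResult, ModelFit]:
    """LRT-select the interaction, then apply the singular-fit fallback."""
    lrt, chosen = lrt_interaction(data, spec, mixed=True)
    final = fallback_if_singular(chosen, data, spec)
    return lrt, final
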