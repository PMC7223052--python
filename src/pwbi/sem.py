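"""Maximum-likelihood estimation of the second-order factor model.

The model, in LISREL-style notation with ``Lambda`` the (p x K) first-order
loading matrix, ``gamma`` the column of K second-order loadings, ``Psi`` the
diagonal of first-order disturbance variances and ``Theta`` the diagonal of
indicator residual variances, implies

    Sigma = Lambda (gamma gamma' + Psi) Lambda' + Theta.

Identification fixes the second-order factor variance to 1 and keeps every
first-order factor at unit total variance (``psi_k = 1 - beta_k**2``), so
the reported solution is standardized throughout. Because every indicator
has a free loading and residual variance the model is scale-invariant, and
the engine fits the sample *correlation* matrix internally: the minimized
discrepancy, chi-square and fit indices are identical to a covariance-metric
fit, and the standardized solution is read off directly. Unstandardized
loadings are recovered from the stored indicator standard deviations.

Estimation minimizes the ML discrepancy

    F(S, Sigma) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

by L-BFGS-B with an analytic gradient; chi-square uses the (n - 1)
multiplier. Standard errors come from the inverse observed information of
the ML objective ((n - 1)/2 * F). Residual variances are bounded below at
1e-6; a solution pinned to that bound is reported as a Heywood case.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model import DEFAULT_MODEL, ModelSpec

_THETA_FLOOR = 1e-6
_BETA_BOUND = 0.9995


@dataclass
class ParameterSet:
    """Parameters of the hierarchical measurement model.

    ``loadings`` (lambda_j) and ``residuals`` (theta_j) are per indicator;
    ``betas`` (second-order loadings) and ``psis`` (disturbance variances)
    per first-order factor. A fitted set is standardized; the indicator
    means/SDs that anchored it are kept for scoring new data.
    """

    loadings: dict[str, float]
    residuals: dict[str, float]
    betas: dict[str, float]
    psis: dict[str, float]
    indicator_means: dict[str, float] | None = None
    indicator_sds: dict[str, float] | None = None

    def validate(self, spec: ModelSpec) -> None:
        for j in spec.indicators:
            if self.residuals[j] <= 0:
                raise ValueError(f"residual variance for {j} must be > 0")
        for k in spec.factors:
            if self.psis[k] < 0:
                raise ValueError(f"disturbance variance for {k} must be >= 0")

    def arrays(self, spec: ModelSpec):
        lam = np.array([self.loadings[j] for j in spec.indicators])
        theta = np.array([self.residuals[j] for j in spec.indicators])
        beta = np.array([self.betas[k] for k in spec.factors])
        psi = np.array([self.psis[k] for k in spec.factors])
        return lam, theta, beta, psi

    def to_dict(self) -> dict:
        return {
            "loadings": dict(self.loadings),
            "residuals": dict(self.residuals),
            "betas": dict(self.betas),
            "psis": dict(self.psis),
            "indicator_means": self.indicator_means,
            "indicator_sds": self.indicator_sds,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        return cls(**{k: data.get(k) for k in (
            "loadings", "residuals", "betas", "psis",
            "indicator_means", "indicator_sds",
        )})

    @classmethod
    def from_population(cls, params, spec: ModelSpec = DEFAULT_MODEL) -> "ParameterSet":
        """Standardized ParameterSet implied by generating PopulationParams."""
        lam = {j: params.first_order_loadings[j] for j in spec.indicators}
        beta = {k: params.second_order_loadings[k] for k in spec.factors}
        return cls(
            loadings=lam,
            residuals={j: 1.0 - lam[j] ** 2 for j in spec.indicators},
            betas=beta,
            psis={k: 1.0 - beta[k] ** 2 for k in spec.factors},
            indicator_means=dict(params.indicator_means),
            indicator_sds=dict(params.indicator_sds),
        )


@dataclass
class FitResult:
    """Fit statistics, convergence status and standard errors."""

    chi_square: float
    df: int
    rmsea: float
    cfi: float
    srmr: float
    loglik: float
    converged: bool
    n_used: int
    se: dict[str, float] = field(default_factory=dict)
    chi_square_baseline: float = float("nan")
    df_baseline: int = 0
    n_free: int = 0
    heywood: list[str] = field(default_factory=list)
    n_iter: int = 0
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "rmsea": self.rmsea,
            "cfi": self.cfi,
            "srmr": self.srmr,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_used": self.n_used,
            "se": dict(self.se),
            "chi_square_baseline": self.chi_square_baseline,
            "df_baseline": self.df_baseline,
            "n_free": self.n_free,
            "heywood": list(self.heywood),
            "n_iter": self.n_iter,
            "message": self.message,
        }


# ---------------------------------------------------------------------------
# Model algebra
# ---------------------------------------------------------------------------


def _loading_matrix(lam: np.ndarray, spec: ModelSpec) -> np.ndarray:
    p, K = len(spec.indicators), len(spec.factors)
    L = np.zeros((p, K))
    findex = {f: k for k, f in enumerate(spec.factors)}
    for j, name in enumerate(spec.indicators):
        L[j, findex[spec.factor_of(name)]] = lam[j]
    return L


def _implied(lam, theta, beta, psi, spec: ModelSpec) -> np.ndarray:
    L = _loading_matrix(lam, spec)
    G = np.outer(beta, beta) + np.diag(psi)
    return L @ G @ L.T + np.diag(theta)


def implied_covariance(params: ParameterSet, spec: ModelSpec = DEFAULT_MODEL) -> np.ndarray:
    """Model-implied covariance Sigma = Lambda (gg' + Psi) Lambda' + Theta.

    Rows/columns follow ``spec.indicators``. Raises if the result is not
    positive definite.
    """
    lam, theta, beta, psi = params.arrays(spec)
    Sigma = _implied(lam, theta, beta, psi, spec)
    # perfectly collinear structures (singular but PSD) are legal; negative
    # curvature means invalid parameters
    if np.linalg.eigvalsh(Sigma).min() < -1e-10:
        raise np.linalg.LinAlgError("implied covariance is not positive semidefinite")
    return Sigma


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Wishart ML discrepancy F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p.

    Nonnegative, and zero exactly when S equals Sigma.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = S.shape[0]
    if S.shape != Sigma.shape or S.shape != (p, p):
        raise ValueError("S and Sigma must be square matrices of equal size")
    sign_s, ld_s = np.linalg.slogdet(S)
    sign_m, ld_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise np.linalg.LinAlgError("singular or indefinite covariance input")
    return float(ld_m + np.trace(np.linalg.solve(Sigma, S)) - ld_s - p)


def fit_indices(
    chi_square: float,
    df: int,
    n: int,
    chi_square_baseline: float,
    df_baseline: int,
    S: np.ndarray,
    Sigma: np.ndarray,
    srmr_diagonal: bool = True,
) -> tuple[float, float, float]:
    """RMSEA, CFI and SRMR from chi-squares and the residual matrix.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))); CFI compares the model's
    noncentrality against the independence baseline; SRMR is the RMS of the
    standardized residual covariances over the lower triangle, including
    the diagonal by default.
    """
    if df <= 0:
        raise ValueError("df must be positive for fit indices")
    rmsea = float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))
    num = max(chi_square - df, 0.0)
    den = max(chi_square_baseline - df_baseline, chi_square - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    d = np.sqrt(np.diag(S))
    resid = (S - Sigma) / np.outer(d, d)
    idx = np.tril_indices_from(resid, k=0 if srmr_diagonal else -1)
    srmr = float(np.sqrt(np.mean(resid[idx] ** 2)))
    return rmsea, float(cfi), srmr


def standardize(params: ParameterSet, S: np.ndarray | None = None,
                spec: ModelSpec = DEFAULT_MODEL) -> ParameterSet:
    """Rescale a solution so all observed and latent variances are 1.

    Factor variances are already unit under the engine's identification, so
    only indicator scales change: lambda_j / sd_j and theta_j / var_j, with
    variances taken from ``S`` when given, else from the implied covariance.
    Standardized second-order loadings are unaffected.
    """
    lam, theta, beta, psi = params.arrays(spec)
    if S is not None:
        var = np.diag(np.asarray(S, dtype=float)).copy()
    else:
        var = np.diag(_implied(lam, theta, beta, psi, spec)).copy()
    if np.any(var <= 0):
        j = spec.indicators[int(np.argmin(var))]
        raise ValueError(f"zero or negative variance for indicator {j}")
    sd = np.sqrt(var)
    return ParameterSet(
        loadings={j: lam[i] / sd[i] for i, j in enumerate(spec.indicators)},
        residuals={j: theta[i] / var[i] for i, j in enumerate(spec.indicators)},
        betas=dict(params.betas),
        psis=dict(params.psis),
        indicator_means=params.indicator_means,
        indicator_sds=dict(
            zip(spec.indicators, sd * np.array(
                [1.0 if params.indicator_sds is None
                 else params.indicator_sds[j] for j in spec.indicators]
            ))
        ) if params.indicator_sds is not None or S is not None else None,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _pack_names(spec: ModelSpec) -> list[str]:
    return (
        [f"lambda:{j}" for j in spec.indicators]
        + [f"beta:{k}" for k in spec.factors]
        + [f"theta:{j}" for j in spec.indicators]
    )


def _objective_factory(R: np.ndarray, spec: ModelSpec, free: np.ndarray,
                       full0: np.ndarray):
    p = len(spec.indicators)
    K = len(spec.factors)
    findex = np.array(
        [list(spec.factors).index(spec.factor_of(j)) for j in spec.indicators]
    )
    sign_r, ld_r = np.linalg.slogdet(R)
    if sign_r <= 0:
        raise np.linalg.LinAlgError("sample matrix is singular or indefinite")

    def split(full):
        return full[:p], full[p:p + K], full[p + K:]

    def fun_grad(x):
        full = full0.copy()
        full[free] = x
        lam, beta, theta = split(full)
        psi = 1.0 - beta**2
        G = np.outer(beta, beta) + np.diag(psi)
        # Lambda G Lambda' via indicator->factor index, avoiding p x K matmuls
        LG = G[findex] * lam[:, None]            # (p, K) rows lam_j * G[k_j]
        Sigma = (LG[:, findex] * lam[None, :])   # (p, p)
        Sigma = Sigma + np.diag(theta)
        sign_m, ld_m = np.linalg.slogdet(Sigma)
        if sign_m <= 0:
            return np.inf, np.zeros(free.sum())
        Sinv = np.linalg.inv(Sigma)
        F = ld_m + np.sum(Sinv * R) - ld_r - p
        M = Sinv - Sinv @ R @ Sinv               # dF = tr(M dSigma)
        # gradients
        Lmat = np.zeros((p, K))
        Lmat[np.arange(p), findex] = lam
        MLG = M @ (Lmat @ G)                      # (p, K)
        g_lam = 2.0 * MLG[np.arange(p), findex]
        A = Lmat.T @ M @ Lmat                     # (K, K)
        g_beta = 2.0 * (A @ beta) - 2.0 * beta * np.diag(A)
        g_theta = np.diag(M).copy()
        g_full = np.concatenate([g_lam, g_beta, g_theta])
        return float(F), g_full[free]

    return fun_grad


def fit(
    S: np.ndarray,
    n: int,
    spec: ModelSpec = DEFAULT_MODEL,
    init: dict | None = None,
    options: dict | None = None,
    fixed: dict[str, float] | None = None,
    means: dict[str, float] | None = None,
) -> tuple[ParameterSet, FitResult]:
    """Fit the second-order model to a sample covariance by ML.

    Parameters
    ----------
    S : sample covariance (or correlation) matrix, ordered as
        ``spec.indicators``.
    n : number of observations behind ``S``; the chi-square uses ``n - 1``.
    init : optional starting values, keys ``lambda`` / ``beta`` / ``theta``
        (scalar applied to all). Defaults: 0.5 / 0.5 / half the indicator
        variance (on the internal correlation metric).
    fixed : optional ``{"beta:MS": 0.0, "lambda:kidmed": 0.3, ...}``
        constraints, expressed on the standardized metric.
    options : ``gtol`` / ``ftol`` / ``maxiter`` / ``srmr_diagonal`` /
        ``compute_se`` overrides.

    Returns the standardized solution and a :class:`FitResult`.
    Non-convergence sets ``converged=False`` rather than raising; residual
    variances pinned at the lower bound are listed by indicator name in
    ``FitResult.heywood``.
    """
    opts = {"gtol": 1e-8, "ftol": 1e-14, "maxiter": 5000,
            "srmr_diagonal": True, "compute_se": True}
    opts.update(options or {})
    S = np.asarray(S, dtype=float)
    p = len(spec.indicators)
    K = len(spec.factors)
    if S.shape != (p, p):
        raise ValueError(f"S must be {p}x{p} for this model spec")
    if n <= p:
        raise ValueError("sample size must exceed the number of indicators")
    if np.linalg.eigvalsh(S).min() <= 0:
        raise np.linalg.LinAlgError("sample covariance is not positive definite")
    if K < 3 and not (fixed and any(k.startswith("beta:") for k in fixed)):
        warnings.warn(
            "second-order loadings are not separately identified with fewer "
            "than three first-order factors", stacklevel=2,
        )

    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)

    names = _pack_names(spec)
    init = init or {}
    full0 = np.concatenate([
        np.full(p, float(init.get("lambda", 0.5))),
        np.full(K, float(init.get("beta", 0.5))),
        np.full(p, float(init.get("theta", 0.5))) * np.diag(R),
    ])
    free = np.ones(len(full0), dtype=bool)
    for key, value in (fixed or {}).items():
        if key not in names:
            raise KeyError(f"unknown parameter {key!r}")
        i = names.index(key)
        free[i] = False
        full0[i] = float(value)

    lower = np.concatenate([
        np.full(p, -10.0), np.full(K, -_BETA_BOUND), np.full(p, _THETA_FLOOR)
    ])
    upper = np.concatenate([
        np.full(p, 10.0), np.full(K, _BETA_BOUND), np.full(p, np.inf)
    ])
    bounds = list(zip(lower[free], upper[free]))

    fun_grad = _objective_factory(R, spec, free, full0)
    res = optimize.minimize(
        fun_grad, full0[free], jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": opts["maxiter"], "ftol": opts["ftol"],
                 "gtol": opts["gtol"], "maxfun": 10 * opts["maxiter"]},
    )
    # polish: restart once from the solution (L-BFGS-B memory reset often
    # buys another digit near flat optima)
    res2 = optimize.minimize(
        fun_grad, res.x, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": opts["maxiter"], "ftol": 1e-16,
                 "gtol": opts["gtol"] * 0.1},
    )
    success = bool(res.success or res2.success)
    if res2.fun <= res.fun:
        res = res2

    # Newton polish on coordinates away from bounds: L-BFGS-B's relative
    # ftol leaves ~1e-8 parameter noise, too coarse for exact invariance
    # properties of the standardized solution
    x_best, f_best = _newton_polish(
        fun_grad, res.x.copy(), float(res.fun), lower[free], upper[free]
    )

    full = full0.copy()
    full[free] = x_best
    lam, beta, theta = full[:p], full[p:p + K], full[p + K:]

    # sign alignment: loading sum positive per factor, beta sum positive
    findex = np.array([list(spec.factors).index(spec.factor_of(j))
                       for j in spec.indicators])
    for k in range(K):
        mask = findex == k
        if lam[mask].sum() < 0:
            lam[mask] *= -1
            beta[k] *= -1
    if beta.sum() < 0:
        beta *= -1
    psi = 1.0 - beta**2

    F_min = f_best
    _, gfree = fun_grad(full[free])
    # projected gradient: components pressing against an active bound are legal
    at_lower = np.isclose(full[free], lower[free], atol=1e-9)
    at_upper = np.isclose(full[free], upper[free], atol=1e-9)
    gproj = gfree.copy()
    gproj[at_lower & (gproj > 0)] = 0.0
    gproj[at_upper & (gproj < 0)] = 0.0
    gnorm = float(np.linalg.norm(gproj, ord=np.inf))
    converged = bool((success or gnorm < 1e-4) and np.isfinite(F_min))

    heywood = [spec.indicators[i] for i in range(p)
               if theta[i] <= _THETA_FLOOR * 2]

    chi2 = (n - 1) * F_min
    n_free = int(free.sum())
    df = p * (p + 1) // 2 - n_free
    sign_r, ld_r = np.linalg.slogdet(R)
    F_base = float(-ld_r)  # independence model on the correlation metric
    chi2_base = (n - 1) * F_base
    df_base = p * (p - 1) // 2

    Sigma_hat = _implied(lam, theta, beta, psi, spec)
    rmsea, cfi, srmr = fit_indices(
        chi2, df, n, chi2_base, df_base, R, Sigma_hat,
        srmr_diagonal=opts["srmr_diagonal"],
    ) if df > 0 else (0.0, 1.0, 0.0)

    # log-likelihood on the original covariance metric
    ld_sigma_cov = np.linalg.slogdet(Sigma_hat)[1] + 2 * np.log(d).sum()
    tr_term = np.sum(np.linalg.inv(Sigma_hat) * R)
    loglik = -0.5 * (n - 1) * (ld_sigma_cov + tr_term + p * np.log(2 * np.pi))

    se: dict[str, float] = {}
    if opts["compute_se"]:
        se_free = _observed_information_se(fun_grad, full[free], n)
        free_names = [nm for nm, f in zip(names, free) if f]
        se = dict(zip(free_names, se_free))

    params = ParameterSet(
        loadings=dict(zip(spec.indicators, lam)),
        residuals=dict(zip(spec.indicators, theta)),
        betas=dict(zip(spec.factors, beta)),
        psis=dict(zip(spec.factors, psi)),
        indicator_means=dict(means) if means else None,
        indicator_sds=dict(zip(spec.indicators, d)),
    )
    result = FitResult(
        chi_square=chi2, df=df, rmsea=rmsea, cfi=cfi, srmr=srmr,
        loglik=float(loglik), converged=converged, n_used=int(n), se=se,
        chi_square_baseline=chi2_base, df_baseline=df_base, n_free=n_free,
        heywood=heywood, n_iter=int(res.nit),
        message=str(res.message),
    )
    return params, result


def _newton_polish(fun_grad, x, f, lower, upper, max_steps: int = 15):
    """Damped Newton refinement of an L-BFGS-B solution.

    Operates only on coordinates strictly inside their bounds (bound-pinned
    residual variances stay put); the Hessian is built by central
    differences of the analytic gradient.
    """
    # near the optimum F changes only at machine precision for parameter
    # moves of ~1e-8, so step acceptance is judged on the (analytic)
    # gradient norm, which stays informative far below that scale
    _, g = fun_grad(x)
    for _ in range(max_steps):
        interior = (x > lower + 1e-8) & (x < upper - 1e-8)
        gi = g[interior]
        gnorm = np.linalg.norm(gi, ord=np.inf) if gi.size else 0.0
        if gi.size == 0 or gnorm < 1e-12:
            break
        m = int(interior.sum())
        idx = np.flatnonzero(interior)
        H = np.empty((m, m))
        h = 1e-6 * np.maximum(1.0, np.abs(x[idx]))
        for a in range(m):
            xp, xm = x.copy(), x.copy()
            xp[idx[a]] += h[a]
            xm[idx[a]] -= h[a]
            _, gp = fun_grad(xp)
            _, gm = fun_grad(xm)
            H[:, a] = (gp[interior] - gm[interior]) / (2 * h[a])
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H, gi)
        except np.linalg.LinAlgError:
            break
        improved = False
        for t in (1.0, 0.5, 0.25, 0.1):
            xn = x.copy()
            xn[idx] = np.clip(x[idx] - t * step, lower[idx], upper[idx])
            fn, gn = fun_grad(xn)
            gn_norm = np.linalg.norm(gn[interior], ord=np.inf)
            if np.isfinite(fn) and (gn_norm < gnorm or fn < f - 1e-12):
                x, f, g = xn, min(f, fn), gn
                improved = True
                break
        if not improved:
            break
    return x, float(f)


def _observed_information_se(fun_grad, x: np.ndarray, n: int) -> np.ndarray:
    """SEs from the inverse observed information of (n-1)/2 * F.

    The Hessian of F is built by central differences of the analytic
    gradient; non-invertible or negative-curvature directions yield NaN.
    """
    m = len(x)
    H = np.zeros((m, m))
    h = 1e-5 * np.maximum(1.0, np.abs(x))
    for i in range(m):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        _, gp = fun_grad(xp)
        _, gm = fun_grad(xm)
        H[:, i] = (gp - gm) / (2 * h[i])
    H = 0.5 * (H + H.T) * (n - 1) / 2.0
    se = np.full(m, np.nan)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        with np.errstate(invalid="ignore"):
            se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
    except np.linalg.LinAlgError:
        pass
    return se


def fit_from_data(
    indicators: pd.DataFrame,
    spec: ModelSpec = DEFAULT_MODEL,
    **kwargs,
) -> tuple[ParameterSet, FitResult]:
    """Fit from an indicator table (complete cases only).

    ``indicators`` holds one row per student with the 14 indicator columns
    (a ``student_id`` column is ignored). Listwise deletion mirrors the
    complete-questionnaire inclusion rule.
    """
    cols = list(spec.indicators)
    data = indicators[cols].astype(float).dropna()
    n = len(data)
    S = np.cov(data.to_numpy(), rowvar=False, ddof=1)
    means = data.mean().to_dict()
    return fit(S, n, spec, means=means, **kwargs)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def save_model(params: ParameterSet, result: FitResult, path,
               extra: dict | None = None) -> None:
    payload = {"params": params.to_dict(), "fit": result.to_dict()}
    if extra:
        payload.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def load_model(path) -> tuple[ParameterSet, dict]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return ParameterSet.from_dict(payload["params"]), payload
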