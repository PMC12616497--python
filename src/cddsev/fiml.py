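"""Full-information maximum-likelihood SEM estimation.

Subjects contribute the multivariate-normal log-density of whatever subset
of the nine indicators they have observed, evaluated under the model-implied
mean and covariance restricted to that subset.  Rows are grouped by
missingness pattern and summarized by per-pattern sufficient statistics
(count, mean, scatter), so one likelihood evaluation costs O(#patterns *
p^3) regardless of cohort size; grouping never changes the value.

The saturated (unstructured mean + covariance) reference likelihood is
maximized by an EM algorithm for the multivariate normal with missing data;
the baseline reference is the independence model, whose FIML solution
factorizes into per-variable observed-data means and ML variances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import OBSERVED_VARS, INSTRUMENTS
from .model import SemModel, implied_moments

log = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))
_PENALTY = 1e15


# ---------------------------------------------------------------------
# inclusion rule

def filter_inclusion(cohort: pd.DataFrame, *, min_scores: int = 2,
                     level: str = "variable") -> pd.DataFrame:
    """Keep baseline rows with at least ``min_scores`` reported scores.

    ``level='variable'`` counts non-missing observed variables (default);
    ``level='instrument'`` counts instruments with at least one reported
    domain.  The excluded count is logged.
    """
    base = cohort[cohort.get("visit", "baseline") == "baseline"]
    obs = base[list(OBSERVED_VARS)]
    if level == "variable":
        counts = obs.notna().sum(axis=1)
    elif level == "instrument":
        counts = sum(
            obs[[c for c in cols if c in obs.columns]].notna().any(axis=1).astype(int)
            for cols in (INSTRUMENTS[i] for i in ("clinician", "caregiver", "sleep", "csbs"))
        )
    else:
        raise ValueError(f"unknown inclusion level {level!r}")
    keep = counts >= min_scores
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.info("inclusion rule excluded %d of %d baseline rows",
                 n_excluded, len(base))
    out = base[keep].reset_index(drop=True)
    out.attrs["n_excluded"] = n_excluded
    return out


# ---------------------------------------------------------------------
# pattern-grouped sufficient statistics

@dataclass
class _Pattern:
    obs: np.ndarray       # indices of observed variables
    n: int
    mean: np.ndarray
    scatter: np.ndarray   # sum (y - mean)(y - mean)^T
    rows: np.ndarray      # raw observed values, n x k (kept for EM / scores)
    row_index: np.ndarray


class PatternData:
    """Rows of an incomplete data matrix grouped by missingness pattern."""

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        self.n_rows, self.p = y.shape
        self.patterns: list[_Pattern] = []
        mask = ~np.isnan(y)
        keys = {}
        for i in range(self.n_rows):
            if not mask[i].any():
                continue
            keys.setdefault(mask[i].tobytes(), []).append(i)
        for key, idx in keys.items():
            m = np.frombuffer(key, dtype=bool)
            obs = np.flatnonzero(m)
            rows = y[np.ix_(idx, obs)]
            mean = rows.mean(axis=0)
            dev = rows - mean
            self.patterns.append(_Pattern(
                obs=obs, n=len(idx), mean=mean, scatter=dev.T @ dev,
                rows=rows, row_index=np.asarray(idx)))
        self.n_used = sum(pat.n for pat in self.patterns)

    @classmethod
    def from_frame(cls, cohort: pd.DataFrame,
                   observed: tuple[str, ...] = OBSERVED_VARS) -> "PatternData":
        return cls(cohort[list(observed)].to_numpy(dtype=float))

    @property
    def complete(self) -> bool:
        return len(self.patterns) == 1 and self.patterns[0].obs.size == self.p


def _loglik_moments(mu: np.ndarray, sigma: np.ndarray, data: PatternData) -> float:
    """Observed-data MVN log-likelihood; -inf if a pattern submatrix is not
    positive definite (inadmissible-theta signal rather than a crash)."""
    total = 0.0
    for pat in data.patterns:
        sub = sigma[np.ix_(pat.obs, pat.obs)]
        try:
            chol = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        d = pat.mean - mu[pat.obs]
        z = np.linalg.solve(chol, d)
        inv_scatter = np.linalg.solve(chol.T, np.linalg.solve(chol, pat.scatter))
        total += -0.5 * (pat.n * (pat.obs.size * _LOG2PI + logdet + z @ z)
                         + np.trace(inv_scatter))
    return float(total)


def fiml_loglik(model: SemModel, theta: np.ndarray,
                cohort: pd.DataFrame | PatternData) -> float:
    """FIML log-likelihood of the cohort at theta.

    Accepts either a cohort frame or pre-grouped :class:`PatternData`.
    Returns -inf for inadmissible theta (non-PD implied pattern submatrix).
    """
    data = cohort if isinstance(cohort, PatternData) else PatternData.from_frame(cohort)
    try:
        im = implied_moments(model, theta)
    except ValueError:
        return -np.inf
    return _loglik_moments(im.mean, im.cov, data)


def _moment_gradients(data: PatternData, mu: np.ndarray, sigma: np.ndarray
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood plus its gradients with respect to (mu, Sigma).

    d l / d Sigma is accumulated over patterns as
    -1/2 [ n A - A (n d d^T + S) A ] with A the inverse pattern submatrix;
    d l / d mu as n A d.  Returns (loglik, g_mu, G_sigma).
    """
    p = data.p
    total = 0.0
    g_mu = np.zeros(p)
    g_sig = np.zeros((p, p))
    for pat in data.patterns:
        o = pat.obs
        sub = sigma[np.ix_(o, o)]
        try:
            chol = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return -np.inf, g_mu, g_sig
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        a = np.linalg.inv(sub)
        d = pat.mean - mu[o]
        ad = a @ d
        m = pat.n * np.outer(d, d) + pat.scatter
        total += -0.5 * (pat.n * (o.size * _LOG2PI + logdet + d @ ad)
                         + np.sum(a * pat.scatter))
        g_mu[o] += pat.n * ad
        g_sig[np.ix_(o, o)] += -0.5 * (pat.n * a - a @ m @ a)
    return float(total), g_mu, g_sig


def fiml_loglik_grad(model: SemModel, theta: np.ndarray, data: PatternData
                     ) -> tuple[float, np.ndarray]:
    """FIML log-likelihood and its analytic gradient in theta.

    The chain rule runs through Sigma = Lambda V Lambda^T + Theta with
    V = (I-B)^-1 Psi (I-B)^-T; every free parameter perturbs Sigma (or mu)
    through a rank-one or rank-two symmetric update, so each derivative is
    a couple of matrix-vector products against the Sigma-gradient.
    """
    try:
        lam_mat, B, psi_mat, theta_diag, nu = model.matrices(theta)
    except ValueError:
        return -np.inf, np.zeros(model.n_params)
    if np.any(theta_diag <= 0):
        return -np.inf, np.zeros(model.n_params)
    L = len(model.latents)
    eye = np.eye(L)
    inv = np.linalg.solve(eye - B, eye)
    V = inv @ psi_mat @ inv.T
    V = (V + V.T) / 2.0
    sigma = lam_mat @ V @ lam_mat.T + np.diag(theta_diag)
    sigma = (sigma + sigma.T) / 2.0

    ll, g_mu, G = _moment_gradients(data, nu, sigma)
    if not np.isfinite(ll):
        return -np.inf, np.zeros(model.n_params)

    lam_v = lam_mat @ V        # p x L
    K = lam_mat @ inv          # p x L
    lat_idx = {l: i for i, l in enumerate(model.latents)}
    obs_idx = {v: i for i, v in enumerate(model.observed)}

    grad = np.empty(model.n_params)
    for j, (kind, key) in enumerate(model._names):
        if kind == "loading":
            i = obs_idx[key]
            l = lat_idx[model.loadings[key][0]]
            grad[j] = 2.0 * G[i, :] @ lam_v[:, l]
        elif kind == "beta":
            src, tgt = key
            u = lam_mat @ inv[:, lat_idx[tgt]]
            w = lam_mat @ V[lat_idx[src], :]
            grad[j] = 2.0 * u @ G @ w
        elif kind == "psi":
            a, b = lat_idx[key[0]], lat_idx[key[1]]
            if a == b:
                grad[j] = K[:, a] @ G @ K[:, a]
            else:
                grad[j] = 2.0 * K[:, a] @ G @ K[:, b]
        elif kind == "resid_var":
            i = obs_idx[key]
            grad[j] = G[i, i]
        else:  # intercept
            grad[j] = g_mu[obs_idx[key]]
    return ll, grad


# ---------------------------------------------------------------------
# saturated and baseline reference models

def saturated_loglik(data: PatternData, *, tol: float = 1e-10,
                     max_iter: int = 5000) -> tuple[float, np.ndarray, np.ndarray]:
    """FIML log-likelihood of the unstructured mean+covariance model.

    Complete data: closed form (sample mean, ML covariance).  Otherwise EM
    for the multivariate normal with missing values, iterated to an
    absolute log-likelihood tolerance.
    Returns (loglik, mu, sigma).
    """
    p = data.p
    n = data.n_used
    if data.complete:
        pat = data.patterns[0]
        mu = pat.mean.copy()
        sigma = pat.scatter / n
        return _loglik_moments(mu, sigma, data), mu, sigma

    # start at available-case means and a diagonal of available variances
    mu = np.zeros(p)
    var = np.ones(p)
    counts = np.zeros(p)
    sums = np.zeros(p)
    sqs = np.zeros(p)
    for pat in data.patterns:
        sums[pat.obs] += pat.rows.sum(axis=0)
        sqs[pat.obs] += (pat.rows ** 2).sum(axis=0)
        counts[pat.obs] += pat.n
    ok = counts > 0
    mu[ok] = sums[ok] / counts[ok]
    var[ok] = np.maximum(sqs[ok] / counts[ok] - mu[ok] ** 2, 1e-8)
    sigma = np.diag(var)

    prev = _loglik_moments(mu, sigma, data)
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for pat in data.patterns:
            o = pat.obs
            m = np.setdiff1d(np.arange(p), o, assume_unique=True)
            x = np.empty((pat.n, p))
            x[:, o] = pat.rows
            if m.size:
                soo = sigma[np.ix_(o, o)]
                smo = sigma[np.ix_(m, o)]
                a = np.linalg.solve(soo, smo.T).T          # m x o
                x[:, m] = mu[m] + (pat.rows - mu[o]) @ a.T
                cond = sigma[np.ix_(m, m)] - a @ smo.T
                sum_xx[np.ix_(m, m)] += pat.n * cond
            sum_x += x.sum(axis=0)
            sum_xx += x.T @ x
        mu = sum_x / n
        sigma = sum_xx / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2.0
        cur = _loglik_moments(mu, sigma, data)
        if not np.isfinite(cur):
            raise RuntimeError("EM produced a non-PD covariance")
        if abs(cur - prev) < tol:
            prev = cur
            break
        prev = cur
    return prev, mu, sigma


def baseline_loglik(data: PatternData) -> float:
    """FIML log-likelihood of the independence model (free means and
    variances, zero covariances).  Factorizes per variable: each variable's
    MLE is its observed-data mean and ML variance."""
    total = 0.0
    for j in range(data.p):
        vals = np.concatenate([
            pat.rows[:, np.flatnonzero(pat.obs == j)].ravel()
            for pat in data.patterns if j in pat.obs
        ]) if any(j in pat.obs for pat in data.patterns) else np.array([])
        nj = vals.size
        if nj == 0:
            continue
        v = max(vals.var(), 1e-12)
        total += -0.5 * nj * (_LOG2PI + np.log(v) + 1.0)
    return float(total)


# ---------------------------------------------------------------------
# fit indices

def fit_indices(chi_square: float, df: int, chi_square_baseline: float,
                df_baseline: int, n: int, *, rmsea_denominator: str = "n-1"
                ) -> dict[str, float]:
    """RMSEA, CFI, TLI and chi^2/df from model and baseline chi-squares.

    RMSEA = sqrt(max(chi2 - df, 0) / (df * (n - 1))); the denominator can
    use ``n`` instead via ``rmsea_denominator='n'`` (software differs; the
    two agree to <0.3% at typical n).  TLI is reported uncapped and is
    undefined (NaN, with a warning) when the baseline ratio is <= 1.
    """
    if df <= 0 or df_baseline <= 0:
        raise ValueError("df and df_baseline must be positive")
    if n <= 1:
        raise ValueError("n must exceed 1")
    denom = (n - 1) if rmsea_denominator == "n-1" else n
    rmsea = float(np.sqrt(max(chi_square - df, 0.0) / (df * denom)))
    num = max(chi_square - df, 0.0)
    den = max(chi_square_baseline - df_baseline, chi_square - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    ratio_b = chi_square_baseline / df_baseline
    if ratio_b <= 1.0:
        warnings.warn("baseline chi^2/df <= 1: TLI undefined", stacklevel=2)
        tli = float("nan")
    else:
        tli = (ratio_b - chi_square / df) / (ratio_b - 1.0)
    return {
        "rmsea": rmsea,
        "cfi": float(cfi),
        "tli": float(tli),
        "chi_square_over_df": chi_square / df,
    }


# ---------------------------------------------------------------------
# fitting

@dataclass
class FitResult:
    model: SemModel
    theta: np.ndarray
    loglik_model: float
    loglik_saturated: float
    loglik_baseline: float
    chi_square: float
    df: int
    chi_square_baseline: float
    df_baseline: int
    chi_square_over_df: float
    rmsea: float
    cfi: float
    tli: float
    n_used: int
    converged: bool
    n_iterations: int
    message: str = ""
    options: dict = field(default_factory=dict)

    def theta_labeled(self) -> dict[str, float]:
        return self.model.theta_dict(self.theta)

    def to_dict(self) -> dict:
        return {
            "theta": self.theta_labeled(),
            "loglik_model": self.loglik_model,
            "loglik_saturated": self.loglik_saturated,
            "loglik_baseline": self.loglik_baseline,
            "chi_square": self.chi_square,
            "df": self.df,
            "chi_square_baseline": self.chi_square_baseline,
            "df_baseline": self.df_baseline,
            "chi_square_over_df": self.chi_square_over_df,
            "rmsea": self.rmsea,
            "cfi": self.cfi,
            "tli": self.tli,
            "n_used": self.n_used,
            "converged": bool(self.converged),
            "n_iterations": self.n_iterations,
            "message": self.message,
            "options": self.options,
        }


def start_values(model: SemModel, data: PatternData) -> np.ndarray:
    """Documented, reproducible starting point: free loadings 1, structural
    coefficients 0.5, residual variances half the pooled available-case
    variances, latent variances half the variance of each latent's first
    indicator, intercepts at available-case means."""
    p = data.p
    counts = np.zeros(p)
    sums = np.zeros(p)
    sqs = np.zeros(p)
    for pat in data.patterns:
        sums[pat.obs] += pat.rows.sum(axis=0)
        sqs[pat.obs] += (pat.rows ** 2).sum(axis=0)
        counts[pat.obs] += pat.n
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    variances = np.where(
        counts > 1, sqs / np.maximum(counts, 1) - means ** 2, 1.0)
    variances = np.maximum(variances, 1e-6)

    first_indicator = {}
    for var in model.observed:
        lat = model.loadings[var][0]
        first_indicator.setdefault(lat, var)
    obs_idx = {v: i for i, v in enumerate(model.observed)}

    psi_start = {}
    for a, b in model.psi_free:
        if a == b:
            psi_start[(a, b)] = 0.5 * variances[obs_idx[first_indicator[a]]]
        else:
            psi_start[(a, b)] = 0.0
    return model.pack(
        loadings={v: 1.0 for v in model.observed},
        beta={e: 0.5 for e in model.structural},
        psi=psi_start,
        resid_var={v: 0.5 * variances[obs_idx[v]] for v in model.observed},
        intercept={v: means[obs_idx[v]] for v in model.observed},
    )


def _column_scales(data: PatternData) -> tuple[np.ndarray, np.ndarray]:
    """Available-case means and SDs per observed variable."""
    p = data.p
    counts = np.zeros(p)
    sums = np.zeros(p)
    sqs = np.zeros(p)
    for pat in data.patterns:
        sums[pat.obs] += pat.rows.sum(axis=0)
        sqs[pat.obs] += (pat.rows ** 2).sum(axis=0)
        counts[pat.obs] += pat.n
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    var = np.where(counts > 1, sqs / np.maximum(counts, 1) - means ** 2, 1.0)
    sds = np.sqrt(np.maximum(var, 1e-12))
    return means, np.where(sds > 0, sds, 1.0)


def _anchor_scales(model: SemModel, sds: np.ndarray) -> np.ndarray:
    """Per-latent scale factor: the SD of the latent's first fixed-loading
    indicator (1 for variance-identified latents)."""
    obs_idx = {v: i for i, v in enumerate(model.observed)}
    t = np.ones(len(model.latents))
    for li, lat in enumerate(model.latents):
        for var in model.observed:
            l, fixed = model.loadings[var]
            if l == lat and fixed is not None:
                t[li] = sds[obs_idx[var]]
                break
    return t


def _scaled_model(model: SemModel, sds: np.ndarray, t: np.ndarray) -> SemModel:
    """Model re-expressed for standardized data y* = (y - c)/s, with each
    latent rescaled by its anchor SD so fixed unit loadings stay fixed."""
    obs_idx = {v: i for i, v in enumerate(model.observed)}
    lat_idx = {l: i for i, l in enumerate(model.latents)}
    loadings = {}
    for var, (lat, fixed) in model.loadings.items():
        if fixed is None:
            loadings[var] = (lat, None)
        else:
            loadings[var] = (lat, fixed * t[lat_idx[lat]] / sds[obs_idx[var]])
    psi_fixed = {
        (a, b): v / (t[lat_idx[a]] * t[lat_idx[b]])
        for (a, b), v in model.psi_fixed.items()
    }
    return SemModel(observed=model.observed, latents=model.latents,
                    loadings=loadings, structural=model.structural,
                    psi_free=model.psi_free, psi_fixed=psi_fixed)


def _unscale_theta(model: SemModel, theta_s: np.ndarray, means: np.ndarray,
                   sds: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Map parameters fitted on the standardized scale back to raw units."""
    obs_idx = {v: i for i, v in enumerate(model.observed)}
    lat_idx = {l: i for i, l in enumerate(model.latents)}
    out = np.array(theta_s, dtype=float)
    for j, (kind, key) in enumerate(model._names):
        if kind == "loading":
            lat = model.loadings[key][0]
            out[j] = theta_s[j] * sds[obs_idx[key]] / t[lat_idx[lat]]
        elif kind == "beta":
            src, tgt = key
            out[j] = theta_s[j] * t[lat_idx[tgt]] / t[lat_idx[src]]
        elif kind == "psi":
            a, b = key
            out[j] = theta_s[j] * t[lat_idx[a]] * t[lat_idx[b]]
        elif kind == "resid_var":
            out[j] = theta_s[j] * sds[obs_idx[key]] ** 2
        else:  # intercept
            out[j] = means[obs_idx[key]] + theta_s[j] * sds[obs_idx[key]]
    return out


def fit_sem(model: SemModel, cohort: pd.DataFrame | PatternData,
            *, rmsea_denominator: str = "n-1", gtol: float = 1e-6,
            ftol: float = 1e-13, max_iter: int = 500,
            theta0: np.ndarray | None = None) -> FitResult:
    """Fit the model by FIML with L-BFGS-B from a documented start.

    Internally each observed variable is standardized by its available-case
    mean and SD (an exact reparameterization: latents are rescaled by their
    anchor-indicator SDs, and estimates are mapped back to raw units), so
    the optimizer works on a well-conditioned O(1) parameter space.
    Variance parameters are bounded below at 1e-8, so inadmissible
    (negative-variance) solutions surface as boundary estimates and trigger
    a warning rather than failing.  Non-convergence is reported in the
    result flags, never silently.
    """
    data = cohort if isinstance(cohort, PatternData) else PatternData.from_frame(
        cohort, model.observed)
    if data.n_used <= model.n_params:
        raise ValueError(
            f"n_used={data.n_used} does not exceed the parameter count "
            f"{model.n_params}")

    means, sds = _column_scales(data)
    t = _anchor_scales(model, sds)
    scaled = _scaled_model(model, sds, t)
    # rebuild the standardized data matrix (NaNs preserved)
    y = np.full((data.n_rows, data.p), np.nan)
    for pat in data.patterns:
        y[np.ix_(pat.row_index, pat.obs)] = pat.rows
    sdata = PatternData((y - means) / sds)

    x0 = (np.asarray(theta0, float) if theta0 is not None
          else start_values(scaled, sdata))
    var_mask = scaled.variance_param_mask()
    bounds = [(1e-8, None) if m else (None, None) for m in var_mask]

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        ll, grad = fiml_loglik_grad(scaled, theta, sdata)
        if not np.isfinite(ll):
            return _PENALTY, np.zeros_like(theta)
        return -ll, -grad

    res = optimize.minimize(
        objective, x0, method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": max_iter, "ftol": ftol, "gtol": gtol,
                 "maxfun": 200000})
    theta_hat = _unscale_theta(model, res.x, means, sds, t)
    ll0 = fiml_loglik(model, _unscale_theta(model, x0, means, sds, t), data)
    ll_model = fiml_loglik(model, theta_hat, data)
    if not res.success:
        log.warning("FIML optimization did not converge: %s", res.message)
    if ll_model < ll0 - 1e-9:
        log.warning("optimizer ended below the starting log-likelihood")
    at_bound = var_mask & np.isclose(res.x, 1e-8)
    if at_bound.any():
        names = [n for n, b in zip(model.param_names(), at_bound) if b]
        warnings.warn(
            f"variance parameters at the admissibility boundary: {names}",
            stacklevel=2)

    ll_sat, _, _ = saturated_loglik(data)
    ll_base = baseline_loglik(data)
    chi2 = max(0.0, 2.0 * (ll_sat - ll_model))
    chi2_b = max(0.0, 2.0 * (ll_sat - ll_base))
    p = data.p
    df_b = p * (p + 3) // 2 - 2 * p
    idx = fit_indices(chi2, model.df, chi2_b, df_b, data.n_used,
                      rmsea_denominator=rmsea_denominator)
    return FitResult(
        model=model, theta=theta_hat,
        loglik_model=ll_model, loglik_saturated=ll_sat, loglik_baseline=ll_base,
        chi_square=chi2, df=model.df,
        chi_square_baseline=chi2_b, df_baseline=df_b,
        chi_square_over_df=idx["chi_square_over_df"],
        rmsea=idx["rmsea"], cfi=idx["cfi"], tli=idx["tli"],
        n_used=data.n_used, converged=bool(res.success),
        n_iterations=int(res.nit), message=str(res.message),
        options={"gtol": gtol, "ftol": ftol, "max_iter": max_iter,
                 "rmsea_denominator": rmsea_denominator},
    )


# ---------------------------------------------------------------------
# factor scores

def factor_scores(model: SemModel, fit: FitResult | np.ndarray,
                  cohort: pd.DataFrame) -> pd.DataFrame:
    """Regression-method factor scores generalized to missingness patterns.

    Each subject's latent scores are the conditional expectation of the
    latent vector given that subject's observed subvector under the fitted
    joint normal.  Subjects with no observed indicator get NaN scores.
    Each latent is sign-oriented so that a larger score moves its anchor
    (first fixed-loading) indicator in the severity direction.
    """
    theta = fit.theta if isinstance(fit, FitResult) else np.asarray(fit, float)
    im = implied_moments(model, theta)
    V, lam = im.latent_cov, im.lam
    cov_ly = V @ lam.T                     # L x p, cov(latents, observed)

    y = cohort[list(model.observed)].to_numpy(dtype=float)
    n = y.shape[0]
    L = len(model.latents)
    scores = np.full((n, L), np.nan)
    n_obs = np.zeros(n, dtype=int)

    mask = ~np.isnan(y)
    keys: dict[bytes, list[int]] = {}
    for i in range(n):
        if mask[i].any():
            keys.setdefault(mask[i].tobytes(), []).append(i)
    for key, idx in keys.items():
        o = np.flatnonzero(np.frombuffer(key, dtype=bool))
        soo = im.cov[np.ix_(o, o)]
        w = np.linalg.solve(soo, cov_ly[:, o].T)      # k x L
        dev = y[np.ix_(idx, o)] - im.mean[o]
        scores[idx] = dev @ w
        n_obs[idx] = o.size

    # orient: cov(latent, anchor indicator) should be positive
    lat_idx = {l: i for i, l in enumerate(model.latents)}
    obs_idx = {v: i for i, v in enumerate(model.observed)}
    for var, (lat, fixed) in model.loadings.items():
        if fixed is not None:
            j = lat_idx[lat]
            if cov_ly[j, obs_idx[var]] < 0:
                scores[:, j] = -scores[:, j]

    out = pd.DataFrame(scores, columns=list(model.latents))
    for col in ("subject_id", "visit"):
        if col in cohort.columns:
            out.insert(0, col, cohort[col].to_numpy())
    out["n_observed_vars"] = n_obs
    return out
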