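"""Linear mixed models with two crossed random intercepts, fitted by REML.

The models used in the dispersal analysis have the form

    y = X beta + Z_1 u_1 + Z_2 u_2 + eps,
    u_k ~ N(0, sigma_k^2 I),   eps_i ~ N(0, sigma^2 / w_i),

with two *crossed* (non-nested) grouping factors — natal territory and
expected recruitment year — and optional positive case weights ``w`` that
scale the residual precision (the convention of the classical mixed-model
software family: a unit-weight observation has residual variance sigma^2).
Weights are normalised to mean 1 internally so that constant weights
reproduce the unweighted fit exactly.

Estimation profiles beta and sigma^2 out of the restricted likelihood and
minimises the profiled criterion over the two variance ratios
theta_k = sigma_k^2 / sigma^2 with a bounded quasi-Newton search
(L-BFGS-B, theta >= 0, deterministic multi-start).  Bounded-at-zero variance
estimates are legal and reported as such (singular fit flag).  Problem sizes
here are a few hundred observations, so dense Cholesky algebra is used
throughout.

Denominator degrees of freedom for coefficient tests use a
Satterthwaite-style approximation: the variance of each coefficient-variance
estimate is obtained from numerical derivatives of the coefficient
covariance with respect to the variance components and the inverse REML
information; where that is unstable (e.g. on a variance boundary) the df
falls back to n - p and is labelled accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = ["CrossedLMMResult", "fit_crossed_lmm", "reml_neg2loglik"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class CrossedLMMResult:
    """REML fit of a crossed random-intercepts linear mixed model."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    sigma2: float                       # residual variance (unit weight)
    varcomp: dict                       # factor -> variance
    n_levels: dict                      # factor -> number of levels
    loglik: float                       # restricted log-likelihood
    n_obs: int
    converged: bool
    singular: bool
    df: np.ndarray | None = None        # Satterthwaite denominator df per coef
    df_method: str = "satterthwaite"

    def coef_table(self) -> pd.DataFrame:
        """Wald tests per coefficient: chi^2 = (estimate/SE)^2 with
        approximate denominator df (p-value from t on those df)."""
        t = self.beta / self.se
        df = self.df if self.df is not None else np.full(len(self.beta), self.n_obs - len(self.beta))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        return pd.DataFrame({
            "term": self.names,
            "estimate": self.beta,
            "se": self.se,
            "chi2": t ** 2,
            "df": df,
            "p": p,
        })

    def varcomp_table(self) -> pd.DataFrame:
        rows = [(k, v, np.sqrt(v), self.n_levels[k]) for k, v in self.varcomp.items()]
        rows.append(("Residual", self.sigma2, np.sqrt(self.sigma2), self.n_obs))
        return pd.DataFrame(rows, columns=["group", "variance", "sd", "n"])


def _indicator(labels) -> tuple[np.ndarray, int]:
    codes, uniq = pd.factorize(np.asarray(labels))
    Z = np.zeros((len(codes), len(uniq)))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z, len(uniq)


def reml_neg2loglik(variances, y, X, Zs, weights=None) -> float:
    """-2 restricted log-likelihood at explicit variances.

    ``variances`` = (sigma_1^2, ..., sigma_K^2, sigma^2).  Kept independent
    of the profiled fitting path so it can serve as a direct-maximisation
    cross-check.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    *vk, ve = variances
    V = np.diag(ve / w)
    for v, Z in zip(vk, Zs):
        V += v * (Z @ Z.T)
    L = linalg.cholesky(V, lower=True)
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_y = linalg.cho_solve((L, True), y)
    Vi_X = linalg.cho_solve((L, True), X)
    XtViX = X.T @ Vi_X
    beta = linalg.solve(XtViX, X.T @ Vi_y, assume_a="pos")
    r = y - X @ beta
    Vi_r = linalg.cho_solve((L, True), r)
    quad = float(r @ Vi_r)
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    return logdet_V + logdet_XtViX + quad + (n - p) * _LOG2PI


def _profiled(theta, y, X, A_list, w_inv):
    """Profiled -2 REML criterion and GLS pieces at variance ratios theta."""
    n, p = X.shape
    V0 = np.diag(w_inv).copy()
    for t, A in zip(theta, A_list):
        if t > 0:
            V0 += t * A
    L = linalg.cholesky(V0, lower=True)
    logdet_V0 = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_y = linalg.cho_solve((L, True), y)
    Vi_X = linalg.cho_solve((L, True), X)
    XtViX = X.T @ Vi_X
    c = linalg.cholesky(XtViX, lower=True)
    logdet_XtViX = 2.0 * np.sum(np.log(np.diag(c)))
    beta = linalg.cho_solve((c, True), X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve((L, True), r))
    sigma2 = max(quad / (n - p), 1e-300)
    crit = ((n - p) * np.log(sigma2) + logdet_V0 + logdet_XtViX
            + (n - p) * (1.0 + _LOG2PI))
    return crit, beta, sigma2, XtViX


def fit_crossed_lmm(y, X, names, groups: dict, weights=None,
                    compute_df: bool = True) -> CrossedLMMResult:
    """Fit y = X beta + sum_k Z_k u_k + eps by REML.

    Parameters
    ----------
    y : response vector.
    X : fixed-effects design matrix (include the intercept column).
    names : column names of X.
    groups : mapping factor name -> label array (one entry per observation);
        each factor gets an independent random intercept.  Factors may be
        crossed.
    weights : optional positive case weights (residual variance sigma^2/w_i);
        normalised to mean 1.
    compute_df : compute Satterthwaite-style denominator df (skippable in
        tight simulation loops).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have different lengths")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        w = w / w.mean()
    w_inv = 1.0 / w

    factor_names = list(groups)
    Zs, n_levels = [], {}
    for fname in factor_names:
        if len(groups[fname]) != n:
            raise ValueError(f"grouping factor {fname} has wrong length")
        Z, k = _indicator(groups[fname])
        if k < 2:
            raise ValueError(f"grouping factor {fname} needs >= 2 levels")
        Zs.append(Z)
        n_levels[fname] = k
    A_list = [Z @ Z.T for Z in Zs]
    K = len(A_list)

    def objective(theta):
        return _profiled(theta, y, X, A_list, w_inv)[0]

    best = None
    for start in ([0.1] * K, [1.0] * K, [0.01] * K):
        res = optimize.minimize(objective, np.asarray(start), method="L-BFGS-B",
                                bounds=[(0.0, None)] * K,
                                options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    theta = np.maximum(best.x, 0.0)
    crit, beta, sigma2, XtViX = _profiled(theta, y, X, A_list, w_inv)
    vcov = sigma2 * linalg.inv(XtViX)
    se = np.sqrt(np.diag(vcov))
    varcomp = {fname: float(t * sigma2) for fname, t in zip(factor_names, theta)}
    singular = bool(np.any(theta <= 1e-10))

    fit = CrossedLMMResult(
        names=list(names), beta=beta, se=se, vcov=vcov, sigma2=float(sigma2),
        varcomp=varcomp, n_levels=n_levels, loglik=-0.5 * crit, n_obs=n,
        converged=bool(best.success), singular=singular,
    )
    if compute_df:
        fit.df, fit.df_method = _satterthwaite_df(fit, y, X, Zs, w)
    return fit


def _satterthwaite_df(fit: CrossedLMMResult, y, X, Zs, w):
    """Approximate denominator df per coefficient.

    df_j = 2 c_j^2 / Var(c_j), c_j = Var(beta_j), with Var(c_j) = g' I^{-1} g
    from the numerical gradient g of c_j w.r.t. the variance components and
    the numerical REML information matrix I.
    """
    n, p = X.shape
    phi = np.array(list(fit.varcomp.values()) + [fit.sigma2])
    K = len(phi)
    fallback = np.full(p, float(n - p))

    def coef_var(ph):
        V = np.diag(ph[-1] / w)
        for v, Z in zip(ph[:-1], Zs):
            V += max(v, 0.0) * (Z @ Z.T)
        L = linalg.cholesky(V, lower=True)
        Vi_X = linalg.cho_solve((L, True), X)
        return np.diag(linalg.inv(X.T @ Vi_X))

    try:
        h = np.maximum(1e-4 * np.abs(phi), 1e-8)
        grads = np.zeros((K, p))
        for k in range(K):
            lo = phi.copy()
            hi = phi.copy()
            hi[k] += h[k]
            if phi[k] - h[k] >= 0:
                lo[k] -= h[k]
                grads[k] = (coef_var(hi) - coef_var(lo)) / (2 * h[k])
            else:  # boundary: one-sided
                grads[k] = (coef_var(hi) - coef_var(phi)) / h[k]

        def f(ph):
            return reml_neg2loglik(ph, y, X, Zs, weights=w) / 2.0

        H = np.zeros((K, K))
        for i in range(K):
            for j in range(i, K):
                hi_, hj = h[i], h[j]
                pp = phi.copy(); pp[i] += hi_; pp[j] += hj
                pm = phi.copy(); pm[i] += hi_
                mp = phi.copy(); mp[j] += hj
                H[i, j] = H[j, i] = (f(pp) - f(pm) - f(mp) + f(phi)) / (hi_ * hj)
        Hinv = np.linalg.pinv(H)
        df = np.empty(p)
        c = coef_var(phi)
        for j in range(p):
            var_c = float(grads[:, j] @ Hinv @ grads[:, j])
            if var_c <= 0 or not np.isfinite(var_c):
                df[j] = n - p
            else:
                df[j] = np.clip(2.0 * c[j] ** 2 / var_c, 1.0, n - p)
        return df, "satterthwaite"
    except Exception:
        return fallback, "residual (fallback)"
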