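"""Casewise (full-information) multivariate-normal likelihood under missingness.

Cases are grouped by missing-data pattern; each pattern stores sufficient
statistics (count, sum, sum of squares) so the log-likelihood and its
analytic gradient cost the same regardless of sample size.  The saturated
(unrestricted mean/covariance) log-likelihood needed for the model chi-square
is maximised by an EM algorithm that runs on the same pattern statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = ["MissingPatternData", "fiml_loglik", "fiml_loglik_grad",
           "casewise_scores", "casewise_logliks", "saturated_loglik",
           "independence_fit"]

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class _Pattern:
    obs: np.ndarray          # observed column indices
    n: int
    sum_y: np.ndarray        # sum of observed rows
    sum_yy: np.ndarray       # sum of outer products
    rows: np.ndarray         # the observed data block (n, len(obs))
    case_index: np.ndarray   # positions in the original case order


@dataclass
class MissingPatternData:
    patterns: list = field(default_factory=list)
    n_cases: int = 0
    n_all_missing: int = 0
    n_variables: int = 0
    columns: list = field(default_factory=list)

    @classmethod
    def from_dataframe(cls, data, columns=None) -> "MissingPatternData":
        """Group a cases x variables table (NaN = missing) by missing pattern.

        Cases missing on every variable are excluded (counted in
        ``n_all_missing``).
        """
        if isinstance(data, pd.DataFrame):
            if columns is not None:
                data = data[list(columns)]
            cols = list(data.columns)
            arr = data.to_numpy(dtype=float)
        else:
            arr = np.asarray(data, dtype=float)
            cols = list(columns) if columns is not None else list(range(arr.shape[1]))
        mask = ~np.isnan(arr)
        keep = mask.any(axis=1)
        out = cls(n_variables=arr.shape[1], columns=cols)
        out.n_all_missing = int((~keep).sum())
        arr, mask = arr[keep], mask[keep]
        out.n_cases = arr.shape[0]
        if out.n_cases == 0:
            raise ValueError("no cases with at least one observed variable")
        # group rows by pattern key
        key = mask @ (1 << np.arange(arr.shape[1], dtype=object))
        order = np.argsort(key, kind="stable")
        key_sorted = key[order]
        breaks = np.flatnonzero(np.r_[True, key_sorted[1:] != key_sorted[:-1]])
        bounds = np.r_[breaks, len(key_sorted)]
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            idx = order[b0:b1]
            obs = np.flatnonzero(mask[idx[0]])
            rows = arr[np.ix_(idx, obs)]
            out.patterns.append(_Pattern(
                obs=obs, n=len(idx), sum_y=rows.sum(axis=0),
                sum_yy=rows.T @ rows, rows=rows, case_index=idx,
            ))
        return out

    @property
    def is_complete(self) -> bool:
        return all(len(p.obs) == self.n_variables for p in self.patterns)


def _pattern_terms(p: _Pattern, mu, sigma):
    """Cholesky, precision, centered sums for one pattern; None if not PD."""
    sub = sigma[np.ix_(p.obs, p.obs)]
    mu_o = mu[p.obs]
    try:
        c, low = linalg.cho_factor(sub, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    W = linalg.cho_solve((c, low), np.eye(len(p.obs)), check_finite=False)
    sum_r = p.sum_y - p.n * mu_o
    Srr = p.sum_yy - np.outer(p.sum_y, mu_o) - np.outer(mu_o, p.sum_y) + p.n * np.outer(mu_o, mu_o)
    return mu_o, W, logdet, sum_r, Srr


def fiml_loglik(data: MissingPatternData, mu, sigma) -> float:
    """Total casewise log-likelihood; -inf if any pattern submatrix is not PD."""
    total = 0.0
    for p in data.patterns:
        t = _pattern_terms(p, mu, sigma)
        if t is None:
            return -np.inf
        _, W, logdet, _, Srr = t
        total += -0.5 * (p.n * (len(p.obs) * LOG2PI + logdet) + np.sum(W * Srr))
    return total


def fiml_loglik_grad(data: MissingPatternData, mu, sigma, dmoms):
    """Log-likelihood and its gradient for parameter-wise (dmu, dSigma) lists."""
    k = len(dmoms)
    grad = np.zeros(k)
    total = 0.0
    for p in data.patterns:
        t = _pattern_terms(p, mu, sigma)
        if t is None:
            return -np.inf, grad
        _, W, logdet, sum_r, Srr = t
        total += -0.5 * (p.n * (len(p.obs) * LOG2PI + logdet) + np.sum(W * Srr))
        u = W @ sum_r
        G = 0.5 * (W @ Srr @ W - p.n * W)
        o = p.obs
        for j, (dmu, dsig) in enumerate(dmoms):
            grad[j] += u @ dmu[o] + np.sum(G * dsig[np.ix_(o, o)])
    return total, grad


def casewise_logliks(data: MissingPatternData, mu, sigma) -> np.ndarray:
    out = np.empty(data.n_cases)
    for p in data.patterns:
        t = _pattern_terms(p, mu, sigma)
        if t is None:
            raise linalg.LinAlgError("covariance submatrix not positive definite")
        mu_o, W, logdet, _, _ = t
        R = p.rows - mu_o
        q = np.einsum("ij,jk,ik->i", R, W, R)
        out[p.case_index] = -0.5 * (len(p.obs) * LOG2PI + logdet + q)
    return out


def casewise_scores(data: MissingPatternData, mu, sigma, dmoms) -> np.ndarray:
    """Per-case gradient of the log-likelihood, cases x parameters."""
    k = len(dmoms)
    out = np.empty((data.n_cases, k))
    for p in data.patterns:
        t = _pattern_terms(p, mu, sigma)
        if t is None:
            raise linalg.LinAlgError("covariance submatrix not positive definite")
        mu_o, W, _, _, _ = t
        U = (p.rows - mu_o) @ W
        o = p.obs
        for j, (dmu, dsig) in enumerate(dmoms):
            ds = dsig[np.ix_(o, o)]
            out[p.case_index, j] = (
                U @ dmu[o]
                + 0.5 * np.einsum("ij,ij->i", U @ ds, U)
                - 0.5 * np.sum(W * ds)
            )
    return out


# ---------------------------------------------------------------------------
# saturated (h1) model by EM


def _pairwise_start(data: MissingPatternData):
    m = data.n_variables
    s1 = np.zeros(m)
    n1 = np.zeros(m)
    for p in data.patterns:
        s1[p.obs] += p.sum_y
        n1[p.obs] += p.n
    if np.any(n1 == 0):
        raise ValueError("a variable is never observed; drop it before fitting")
    mu = s1 / n1
    cov = np.zeros((m, m))
    npair = np.zeros((m, m))
    for p in data.patterns:
        o = p.obs
        d = p.sum_yy - np.outer(p.sum_y, mu[o]) - np.outer(mu[o], p.sum_y) + p.n * np.outer(mu[o], mu[o])
        cov[np.ix_(o, o)] += d
        npair[np.ix_(o, o)] += p.n
    with np.errstate(invalid="ignore"):
        cov = np.where(npair > 0, cov / np.maximum(npair, 1), 0.0)
    # force PD: shrink off-diagonal toward zero until the smallest eigenvalue clears
    d = np.sqrt(np.clip(np.diag(cov), 1e-8, None))
    for lam in (1.0, 0.9, 0.7, 0.5, 0.2, 0.0):
        trial = np.diag(np.diag(cov)) + lam * (cov - np.diag(np.diag(cov)))
        if np.min(np.linalg.eigvalsh(trial)) > 1e-8 * np.max(d) ** 2:
            return mu, trial
    return mu, np.diag(np.clip(np.diag(cov), 1e-8, None))


def _standardized_view(data: MissingPatternData):
    """Per-column available-case standardization of the pattern statistics.

    Returns ``(new_data, shift, scale, n_obs_per_col)``.  Running the
    saturated fit on the standardized view makes its result exactly
    equivariant to linear rescalings of the input columns (the raw-scale
    log-likelihood differs only by the Jacobian term sum_j n_j log s_j).
    """
    m = data.n_variables
    s1 = np.zeros(m)
    s2 = np.zeros(m)
    n1 = np.zeros(m)
    for p in data.patterns:
        s1[p.obs] += p.sum_y
        s2[p.obs] += np.diag(p.sum_yy)
        n1[p.obs] += p.n
    if np.any(n1 == 0):
        raise ValueError("a variable is never observed; drop it before fitting")
    shift = s1 / n1
    scale = np.sqrt(np.clip(s2 / n1 - shift**2, 1e-12, None))
    out = MissingPatternData(n_cases=data.n_cases, n_all_missing=data.n_all_missing,
                             n_variables=m, columns=list(data.columns))
    for p in data.patterns:
        o = p.obs
        mo, so = shift[o], scale[o]
        rows = (p.rows - mo) / so
        sy = (p.sum_y - p.n * mo) / so
        syy = (p.sum_yy - np.outer(p.sum_y, mo) - np.outer(mo, p.sum_y)
               + p.n * np.outer(mo, mo)) / np.outer(so, so)
        out.patterns.append(_Pattern(obs=o, n=p.n, sum_y=sy, sum_yy=syy,
                                     rows=rows, case_index=p.case_index))
    return out, shift, scale, n1


def _mu_sigma_grad(data: MissingPatternData, mu, sigma):
    """Gradient of the FIML log-likelihood with respect to (mu, Sigma)."""
    m = data.n_variables
    gmu = np.zeros(m)
    G = np.zeros((m, m))
    for p in data.patterns:
        t = _pattern_terms(p, mu, sigma)
        if t is None:
            return None, None
        _, W, _, sum_r, Srr = t
        o = p.obs
        gmu[o] += W @ sum_r
        G[np.ix_(o, o)] += 0.5 * (W @ Srr @ W - p.n * W)
    return gmu, G


def _saturated_polish(data: MissingPatternData, mu, sigma, gtol=1e-10, maxiter=20000):
    """Quasi-Newton maximisation of the unrestricted (mu, Sigma) likelihood,
    parameterised by mu and the log-Cholesky factor of Sigma."""
    from scipy import optimize

    m = data.n_variables
    n = data.n_cases
    tril = np.tril_indices(m)
    diag_pos = np.where(tril[0] == tril[1])[0]

    def pack(mu, sigma):
        L = np.linalg.cholesky(sigma)
        v = L[tril].copy()
        v[diag_pos] = np.log(np.diag(L))
        return np.r_[mu, v]

    def unpack(x):
        mu = x[:m]
        L = np.zeros((m, m))
        L[tril] = x[m:]
        np.fill_diagonal(L, np.exp(np.diag(L)))
        return mu, L

    def objective(x):
        mu, L = unpack(x)
        sigma = L @ L.T
        ll = fiml_loglik(data, mu, sigma)
        if not np.isfinite(ll):
            return 1e10, np.zeros_like(x)
        gmu, G = _mu_sigma_grad(data, mu, sigma)
        gL = 2.0 * G @ L
        gv = gL[tril].copy()
        gv[diag_pos] = np.diag(gL) * np.diag(L)
        return -ll / n, -np.r_[gmu, gv] / n

    res = optimize.minimize(objective, pack(mu, sigma), jac=True, method="L-BFGS-B",
                            options={"maxiter": maxiter, "maxfun": 2 * maxiter,
                                     "ftol": 1e-15, "gtol": gtol})
    mu, L = unpack(res.x)
    sigma = L @ L.T
    return fiml_loglik(data, mu, sigma), mu, sigma


def saturated_loglik(data: MissingPatternData, tol: float = 1e-8, max_iter: int = 50):
    """Maximised unrestricted-MVN log-likelihood under missingness.

    A short EM run (monotone, safe far from the optimum) stabilises the
    pairwise-deleted start, and a quasi-Newton polish on (mu, log-Cholesky
    Sigma) drives the gradient to numerical zero — plain EM can need tens of
    thousands of iterations on heavily missing data.  Returns
    ``(loglik, mu, sigma)`` on the original data scale.  On complete data the
    first EM step already lands on the sample mean and 1/n ML covariance.
    """
    sdata, shift, scale, n1 = _standardized_view(data)
    jacobian = float(np.sum(n1 * np.log(scale)))
    mu, sigma = _pairwise_start(sdata)
    m = data.n_variables
    n = data.n_cases
    ll_old = fiml_loglik(sdata, mu, sigma)
    if not np.isfinite(ll_old):
        sigma = np.diag(np.diag(sigma))
        ll_old = fiml_loglik(sdata, mu, sigma)
    for _ in range(max_iter):
        Ey = np.zeros(m)
        Eyy = np.zeros((m, m))
        for p in sdata.patterns:
            o = p.obs
            mis = np.setdiff1d(np.arange(m), o, assume_unique=True)
            mu_o = mu[o]
            sum_r = p.sum_y - p.n * mu_o
            Srr = (p.sum_yy - np.outer(p.sum_y, mu_o) - np.outer(mu_o, p.sum_y)
                   + p.n * np.outer(mu_o, mu_o))
            Ey[o] += p.sum_y
            Eyy[np.ix_(o, o)] += p.sum_yy
            if len(mis) == 0:
                continue
            c, low = linalg.cho_factor(sigma[np.ix_(o, o)], lower=True, check_finite=False)
            B = linalg.cho_solve((c, low), sigma[np.ix_(o, mis)], check_finite=False).T
            C = sigma[np.ix_(mis, mis)] - B @ sigma[np.ix_(o, mis)]
            sum_m = p.n * mu[mis] + B @ sum_r
            Ey[mis] += sum_m
            # sum_i y_i r_i' = sum_yy - sum_y mu_o' = Srr + mu_o sum_r'
            Sym = np.outer(p.sum_y, mu[mis]) + (Srr + np.outer(mu_o, sum_r)) @ B.T
            Eyy[np.ix_(o, mis)] += Sym
            Eyy[np.ix_(mis, o)] += Sym.T
            Smm = (p.n * np.outer(mu[mis], mu[mis]) + np.outer(mu[mis], sum_r) @ B.T
                   + B @ np.outer(sum_r, mu[mis]) + B @ Srr @ B.T + p.n * C)
            Eyy[np.ix_(mis, mis)] += Smm
        mu = Ey / n
        sigma = Eyy / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        ll = fiml_loglik(sdata, mu, sigma)
        if not np.isfinite(ll):
            raise linalg.LinAlgError("EM produced a non-PD covariance")
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            break
        ll_old = ll
    ll, mu, sigma = _saturated_polish(sdata, mu, sigma)
    mu_raw = shift + scale * mu
    sigma_raw = sigma * np.outer(scale, scale)
    return ll - jacobian, mu_raw, sigma_raw


def independence_fit(data: MissingPatternData):
    """FIML baseline (independence) model: free means/variances, zero covariances.

    With a diagonal covariance the casewise likelihood factorises per
    variable, so available-case means and 1/n variances are the exact FIML
    MLEs; returned as ``(loglik, n_params)``.
    """
    m = data.n_variables
    s1 = np.zeros(m)
    s2 = np.zeros(m)
    n1 = np.zeros(m)
    for p in data.patterns:
        s1[p.obs] += p.sum_y
        s2[p.obs] += np.diag(p.sum_yy)
        n1[p.obs] += p.n
    mu = s1 / n1
    var = s2 / n1 - mu**2
    ll = float(np.sum(-0.5 * n1 * (LOG2PI + np.log(var) + 1.0)))
    return ll, 2 * m
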