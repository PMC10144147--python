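"""FIML estimation of a moment structure: StructuralModel / SEMResults.

``StructuralModel`` pairs a :class:`MomentStructure` with a cases x
variables table and maximises the casewise (full-information) normal
log-likelihood by L-BFGS over an unconstrained internal parameterisation
(log-SDs for variance parameters, log-Cholesky for a fully free latent
covariance).  ``fit()`` returns a :class:`SEMResults` carrying estimates,
naive (inverse observed information) and Huber-White sandwich standard
errors, the model chi-square against the EM-maximised saturated model, TLI,
RMSEA with confidence interval, AIC and convergence diagnostics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from . import numdiff
from .indices import FitIndices, fit_indices
from .likelihood import (MissingPatternData, casewise_scores, fiml_loglik,
                         fiml_loglik_grad, independence_fit, saturated_loglik)
from .structure import MomentStructure

__all__ = ["StructuralModel", "SEMResults", "sandwich_se"]

_INFEASIBLE = 1e10
GRAD_TOL = 1e-5      # inf-norm of the mean-loglik gradient
LOGLIK_RELTOL = 1e-8


class StructuralModel:
    """A moment structure bound to data, ready to fit by FIML."""

    def __init__(self, structure: MomentStructure, data, columns=None):
        self.structure = structure
        if isinstance(data, pd.DataFrame):
            cols = columns or [c for c in structure.manifest_names if c in data.columns]
            if list(cols) != list(structure.manifest_names):
                missing = set(structure.manifest_names) - set(data.columns)
                raise ValueError(f"data lacks manifest columns: {sorted(missing)}")
            frame = data[list(structure.manifest_names)]
        else:
            frame = pd.DataFrame(np.asarray(data, dtype=float), columns=structure.manifest_names)
        self._col_stats = (frame.mean().to_numpy(), frame.var(ddof=0).to_numpy())
        self.data = MissingPatternData.from_dataframe(frame)
        m = structure.n_manifest
        self.n_moments = m + m * (m + 1) // 2
        self.df = self.n_moments - structure.n_free
        if self.df < 0:
            raise ValueError(
                f"negative degrees of freedom: {structure.n_free} free parameters, "
                f"{self.n_moments} distinct sample moments")

    # ------------------------------------------------------------------
    def loglik(self, theta_nat) -> float:
        mu, sigma = self.structure.implied_moments(theta_nat)
        return fiml_loglik(self.data, mu, sigma)

    def loglik_grad(self, theta, internal: bool = False):
        mu, sigma, dm = self.structure.moment_derivatives(theta, internal=internal)
        return fiml_loglik_grad(self.data, mu, sigma, dm)

    def _objective(self, theta_int):
        n = self.data.n_cases
        ll, grad = self.loglik_grad(theta_int, internal=True)
        if not np.isfinite(ll):
            return _INFEASIBLE, np.zeros_like(np.asarray(theta_int))
        return -ll / n, -grad / n

    def default_start(self) -> np.ndarray:
        return self.structure.default_start(self._col_stats)

    def expected_information(self, theta_nat) -> np.ndarray:
        """Expected (Fisher) information of the total log-likelihood."""
        s = self.structure
        mu, sigma, dm = s.moment_derivatives(theta_nat, internal=False)
        p = len(dm)
        info = np.zeros((p, p))
        for pat in self.data.patterns:
            o = pat.obs
            W = linalg.inv(sigma[np.ix_(o, o)])
            dmu_o = np.column_stack([d[0][o] for d in dm])
            WD = [W @ d[1][np.ix_(o, o)] for d in dm]
            info += pat.n * (dmu_o.T @ W @ dmu_o)
            for j in range(p):
                for k in range(j + 1):
                    v = 0.5 * np.sum(WD[j] * WD[k].T)
                    info[j, k] += pat.n * v
                    if j != k:
                        info[k, j] += pat.n * v
        return info

    # ------------------------------------------------------------------
    def fit(self, start=None, multi_start=None, maxiter: int = 3000,
            compute_se: bool = True, compute_indices: bool = True,
            saturated=None, baseline=None,
            se_information: str = "observed") -> "SEMResults":
        """Maximise the FIML log-likelihood and assemble results.

        ``start`` is a natural-parameter vector (or dict of overrides);
        ``multi_start`` an optional list of such vectors — every terminal
        point is recorded and the best kept.  ``saturated``/``baseline`` let
        callers share the (data-only) reference log-likelihoods across
        models fit to the same table.
        """
        s = self.structure
        if isinstance(start, dict):
            base = self.default_start()
            d = dict(zip(s.param_names, base))
            d.update(start)
            start = np.asarray([d[p] for p in s.param_names])
        starts = [start if start is not None else self.default_start()]
        if multi_start is not None:
            starts = list(multi_start)

        terminals = []
        for st in starts:
            x0 = s.to_internal(np.asarray(st, dtype=float))
            res = optimize.minimize(
                self._objective, x0, jac=True, method="L-BFGS-B",
                options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                         "ftol": 1e-13, "gtol": 1e-9})
            # one restart from the terminal point tightens the gradient norm
            res2 = optimize.minimize(
                self._objective, res.x, jac=True, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-10})
            if res2.fun <= res.fun:
                res = res2
            terminals.append(res)
        best = min(terminals, key=lambda r: r.fun)
        theta_int = best.x
        theta_nat = s.to_natural(theta_int)
        n = self.data.n_cases
        ll = -best.fun * n

        _, g_int = self._objective(theta_int)
        grad_norm = float(np.max(np.abs(g_int)))
        converged = grad_norm < GRAD_TOL and best.fun < _INFEASIBLE / 2

        se_naive = se_robust = None
        cov_naive = cov_rob = None
        info_pd = True
        H = None
        if compute_se:
            if se_information == "expected":
                H = self.expected_information(theta_nat)
            else:
                def grad_nat(tn):
                    _, g = self.loglik_grad(tn, internal=False)
                    return g
                H = -numdiff.hessian_from_grad(grad_nat, theta_nat, h=1e-5)
            try:
                Hc = linalg.cho_factor(H)
                Hinv = linalg.cho_solve(Hc, np.eye(len(theta_nat)))
            except linalg.LinAlgError:
                info_pd = False
                Hinv = np.linalg.pinv(H)
            se_naive = np.sqrt(np.clip(np.diag(Hinv), 0.0, None))
            mu, sigma, dm = s.moment_derivatives(theta_nat, internal=False)
            scores = casewise_scores(self.data, mu, sigma, dm)
            B = scores.T @ scores
            cov_rob = Hinv @ B @ Hinv
            cov_naive = Hinv
            se_robust = np.sqrt(np.clip(np.diag(cov_rob), 0.0, None))
            converged = converged and info_pd

        chi2 = df = chi2_b = df_b = None
        indices = None
        ll_sat = saturated
        if compute_indices:
            if ll_sat is None:
                ll_sat, _, _ = saturated_loglik(self.data)
            if baseline is None:
                baseline = independence_fit(self.data)
            ll_base, p_base = baseline
            chi2 = max(2.0 * (ll_sat - ll), 0.0)
            df = self.df
            chi2_b = max(2.0 * (ll_sat - ll_base), 0.0)
            df_b = self.n_moments - p_base
            if df > 0 and df_b > 0:
                indices = fit_indices(chi2, df, chi2_b, df_b, n)

        if not converged:
            warnings.warn(
                f"model did not converge (grad norm {grad_norm:.2e}, "
                f"information PD: {info_pd})")

        return SEMResults(
            model=self, params=pd.Series(theta_nat, index=s.param_names),
            se_naive=None if se_naive is None else pd.Series(se_naive, index=s.param_names),
            se_robust=None if se_robust is None else pd.Series(se_robust, index=s.param_names),
            llf=float(ll), n_params=s.n_free, n_cases=n,
            chi2=chi2, df=self.df, chi2_baseline=chi2_b, df_baseline=df_b,
            indices=indices, converged=bool(converged), grad_norm=grad_norm,
            info_pd=info_pd, observed_info=H, cov_naive=cov_naive, cov_robust=cov_rob,
            multi_start_logliks=[-t.fun * n for t in terminals],
            saturated_llf=ll_sat,
        )


@dataclass
class SEMResults:
    """Estimates, uncertainties and fit diagnostics of a FIML fit."""

    model: StructuralModel
    params: pd.Series
    se_naive: pd.Series | None
    se_robust: pd.Series | None
    llf: float
    n_params: int
    n_cases: int
    chi2: float | None
    df: int
    chi2_baseline: float | None
    df_baseline: int | None
    indices: FitIndices | None
    converged: bool
    grad_norm: float
    info_pd: bool = True
    observed_info: np.ndarray | None = None
    cov_naive: np.ndarray | None = None
    cov_robust: np.ndarray | None = None
    multi_start_logliks: list = field(default_factory=list)
    saturated_llf: float | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params

    @property
    def tli(self):
        return None if self.indices is None else self.indices.tli

    @property
    def rmsea(self):
        return None if self.indices is None else self.indices.rmsea

    @property
    def rmsea_ci(self):
        return None if self.indices is None else self.indices.rmsea_ci

    # ------------------------------------------------------------------
    def matrices(self):
        return self.model.structure.fill(self.params.to_numpy())

    def implied_moments(self):
        return self.model.structure.implied_moments(self.params.to_numpy())

    def latent_correlations(self) -> pd.DataFrame:
        _, _, _, psi, _ = self.matrices()
        sd = np.sqrt(np.clip(np.diag(psi), 1e-300, None))
        names = self.model.structure.latent_names
        return pd.DataFrame(psi / np.outer(sd, sd), index=names, columns=names)

    def standardized_loadings(self) -> pd.DataFrame:
        nu, lam, alpha, psi, theta = self.matrices()
        sigma = lam @ psi @ lam.T + theta
        sd_m = np.sqrt(np.diag(sigma))
        sd_l = np.sqrt(np.clip(np.diag(psi), 0.0, None))
        std = lam * sd_l[None, :] / sd_m[:, None]
        return pd.DataFrame(std, index=self.model.structure.manifest_names,
                            columns=self.model.structure.latent_names)

    def wald_test(self, alpha: float = 0.005, robust: bool = True) -> pd.DataFrame:
        se = self.se_robust if robust else self.se_naive
        if se is None:
            raise ValueError("fit was run without standard errors")
        z = self.params / se.replace(0.0, np.nan)
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "estimate": self.params, "se": se, "z": z, "p": p,
            "sig": np.where(p < alpha, "*", ""),
        })

    # ------------------------------------------------------------------
    def fit_line(self, label: str = "model") -> str:
        """One Table-2-style row: chi2(df), TLI, RMSEA [95% CI], AIC."""
        if self.indices is None:
            return f"{label:<55s} (no fit indices computed)  AIC={self.aic:,.0f}"
        lo, hi = self.rmsea_ci
        flag = "" if self.converged else "  [NOT CONVERGED]"
        return (f"{label:<55s} {self.chi2:8.0f} ({self.df:d})  "
                f"TLI={self.tli:.3f}  RMSEA={self.rmsea:.3f} "
                f"[{lo:.3f}, {hi:.3f}]  AIC={self.aic:,.0f}{flag}")

    def summary(self, alpha: float = 0.005) -> str:
        lines = [
            "FIML structural model results",
            "=" * 78,
            f"n cases: {self.n_cases}   free parameters: {self.n_params}   "
            f"df: {self.df}   converged: {self.converged}",
            f"loglik: {self.llf:.3f}   AIC: {self.aic:.1f}   "
            f"grad norm: {self.grad_norm:.2e}",
        ]
        if self.indices is not None:
            lo, hi = self.rmsea_ci
            lines.append(
                f"chi2({self.df}) = {self.chi2:.1f}   TLI = {self.tli:.3f}   "
                f"RMSEA = {self.rmsea:.3f} [{lo:.3f}, {hi:.3f}]")
        lines.append("-" * 78)
        if self.se_robust is not None:
            tab = self.wald_test(alpha=alpha)
            naive = self.se_naive
            lines.append(f"{'parameter':<24s}{'estimate':>10s}{'se(naive)':>11s}"
                         f"{'se(robust)':>11s}{'z':>9s}{'p':>9s}")
            for name, row in tab.iterrows():
                lines.append(
                    f"{name:<24s}{row.estimate:>10.3f}{naive[name]:>11.3f}"
                    f"{row.se:>11.3f}{row.z:>9.2f}{row.p:>9.3g} {row.sig}")
        else:
            for name, val in self.params.items():
                lines.append(f"{name:<24s}{val:>10.3f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        obj = {
            "params": self.params.to_dict(),
            "se_naive": None if self.se_naive is None else self.se_naive.to_dict(),
            "se_robust": None if self.se_robust is None else self.se_robust.to_dict(),
            "loglik": self.llf, "n_params": self.n_params, "n_cases": self.n_cases,
            "chi2": self.chi2, "df": self.df,
            "chi2_baseline": self.chi2_baseline, "df_baseline": self.df_baseline,
            "tli": self.tli, "rmsea": self.rmsea,
            "rmsea_ci": None if self.rmsea_ci is None else list(self.rmsea_ci),
            "aic": self.aic, "converged": self.converged, "grad_norm": self.grad_norm,
        }
        return json.dumps(obj, indent=1)


def sandwich_se(structure: MomentStructure, data: MissingPatternData, theta_hat) -> np.ndarray:
    """Huber-White robust SEs at a converged optimum (natural parameters).

    ``A`` is minus the average casewise Hessian (observed information / n,
    by central differences of the analytic gradient); ``B`` the average
    outer product of casewise scores; the sandwich is A^-1 B A^-1 / n.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    n = data.n_cases

    def grad_nat(tn):
        mu, sigma, dm = structure.moment_derivatives(tn, internal=False)
        _, g = fiml_loglik_grad(data, mu, sigma, dm)
        return g

    A = -numdiff.hessian_from_grad(grad_nat, theta_hat, h=1e-5) / n
    cond = np.linalg.cond(A)
    if cond > 1e12:
        raise linalg.LinAlgError(f"A-matrix numerically singular (condition number {cond:.2e})")
    mu, sigma, dm = structure.moment_derivatives(theta_hat, internal=False)
    scores = casewise_scores(data, mu, sigma, dm)
    B = scores.T @ scores / n
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv / n
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))
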