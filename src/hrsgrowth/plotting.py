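"""Optional convenience plot: group-average and individual trajectories.

A spaghetti plot of empirical-Bayes individual trajectories around the
estimated mean trajectory, per process, on the age-bin grid.
"""

from __future__ import annotations

import numpy as np

from .trajectory import BIN_LOWERS, bin_column, time_code

__all__ = ["empirical_bayes_coefficients", "plot_trajectories"]


def empirical_bayes_coefficients(result, matrix) -> np.ndarray:
    """Posterior-mean growth coefficients per person given observed bins:
    E[eta | y_o] = alpha + Psi Lam_o' Sigma_oo^-1 (y_o - mu_o)."""
    st = result.model.structure
    nu, lam, alpha, psi, theta = result.matrices()
    mu, sigma = result.implied_moments()
    Y = matrix.data[st.manifest_names].to_numpy()
    out = np.full((Y.shape[0], st.n_latent), np.nan)
    for i in range(Y.shape[0]):
        o = np.flatnonzero(~np.isnan(Y[i]))
        if len(o) == 0:
            continue
        W = np.linalg.inv(sigma[np.ix_(o, o)])
        out[i] = alpha + psi @ lam[o].T @ W @ (Y[i, o] - mu[o])
    return out


def plot_trajectories(result, matrix, process: str, n_persons: int = 300,
                      ax=None, seed: int = 0):
    """Fig-1-style spaghetti plot for one process; returns the axis."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    st = result.model.structure
    spec = getattr(result, "spec", None)
    names = [n for n in st.latent_names if n.startswith(process)]
    cols = [st.latent_names.index(n) for n in names]
    s = time_code(BIN_LOWERS)
    if len(names) == 3:
        X = np.column_stack([np.ones_like(s), np.minimum(s, 0), np.maximum(s, 0)])
    elif len(names) == 2:
        X = np.column_stack([np.ones_like(s), s])
    else:
        X = np.ones((len(s), 1))
    coeffs = empirical_bayes_coefficients(result, matrix)[:, cols]
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(coeffs), size=min(n_persons, len(coeffs)), replace=False)
    ages = np.asarray(BIN_LOWERS, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    # only draw each person over their observed age range
    obs = matrix.data[[bin_column(process, b) for b in BIN_LOWERS]].notna().to_numpy()
    for i in keep:
        j = np.flatnonzero(obs[i])
        if len(j) == 0 or np.any(np.isnan(coeffs[i])):
            continue
        lo, hi = j.min(), j.max() + 1
        ax.plot(ages[lo:hi], X[lo:hi] @ coeffs[i], lw=0.4, alpha=0.35)
    mean_coeffs = np.array([result.params[f"mean_{n}"] for n in names])
    ax.plot(ages, X @ mean_coeffs, "k--", lw=2.2, label="group average")
    ax.set_xlabel("age (years, bin lower edge)")
    ax.set_ylabel(f"{process} factor score (age-70 SD units)")
    ax.legend(frameon=False)
    return ax
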