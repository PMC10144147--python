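"""Synthetic accelerated-longitudinal panels with known growth ground truth.

The generator draws person-level growth coefficients from a multivariate
normal, evaluates each process's piecewise-linear (or linear) trajectory at
the person's age per wave, adds correlated occasion residuals, and — for the
item-level generator — maps the occasion-level latent states through a
linear measurement model.  Count-type items are rounded and clipped to their
scale range, which reproduces the positive skew of self-reported
functional-limitation counts (most respondents report zero difficulties).

Attrition is monotone: once a person misses a wave they stay missing.  By
default dropout can be made missing-at-random (MAR) on the person's current
functional-limitation state via a logistic model, with the MCAR special
case at coefficient zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError, GrowthConfig, MeasurementConfig, PanelDesign

__all__ = [
    "draw_growth_coefficients",
    "latent_value_at_age",
    "generate_score_panel",
    "generate_item_panel",
]


def draw_growth_coefficients(config: GrowthConfig, n: int, rng) -> np.ndarray:
    """Draw ``n`` rows of person growth coefficients (columns = latent_names).

    ``rng`` may be an integer seed or a ``numpy.random.Generator``.
    """
    config.validate()
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(rng)
    cov = config.cov_matrix()
    mean = np.asarray(config.latent_means, dtype=float)
    # eigen factor rather than Cholesky: tolerates semidefinite (sd = 0) configs
    w, V = np.linalg.eigh(cov)
    if np.min(w) < -1e-10:
        raise ConfigError("latent covariance is not positive semidefinite")
    root = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, len(mean)))
    return mean + z @ root.T


def latent_value_at_age(coeffs: np.ndarray, ages, config: GrowthConfig) -> dict:
    """Evaluate each process's trajectory at the given ages.

    With ``s = (age - knot) / 10`` decades, a spline process contributes
    ``i + s1*min(s,0) + s2*max(s,0)`` and a linear process ``i + s_lin*s``.
    ``coeffs`` is (n, k) with columns ordered as ``config.latent_names``;
    ``ages`` broadcasts against its rows.  Returns ``{process: values}``.
    """
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 40) or np.any(ages > 95):
        raise ConfigError("ages outside the supported 40-95 range")
    s = (ages - config.knot_age) / 10.0
    idx = {name: j for j, name in enumerate(config.latent_names)}
    out = {}
    for proc in config.processes:
        val = coeffs[:, idx[f"{proc}_i"]] * np.ones_like(s)
        if f"{proc}_s1" in idx:
            val = val + coeffs[:, idx[f"{proc}_s1"]] * np.minimum(s, 0.0)
            val = val + coeffs[:, idx[f"{proc}_s2"]] * np.maximum(s, 0.0)
        elif f"{proc}_s" in idx:
            val = val + coeffs[:, idx[f"{proc}_s"]] * s
        out[proc] = val
    return out


def _baseline_ages(design: PanelDesign, rng) -> np.ndarray:
    lo, hi = design.baseline_age_range
    a = (lo - design.baseline_age_mean) / design.baseline_age_sd
    b = (hi - design.baseline_age_mean) / design.baseline_age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=design.baseline_age_mean, scale=design.baseline_age_sd,
        size=design.n_persons, random_state=rng,
    )
    # HRS reports age in whole years at assessment
    return np.floor(ages) if design.integer_ages else ages


def _occasion_residual_cov(growth: GrowthConfig) -> np.ndarray:
    procs = growth.processes
    sds = np.array([growth.residual_sds[p] for p in procs])
    cov = np.diag(sds**2)
    if len(procs) == 2:
        cov[0, 1] = cov[1, 0] = growth.residual_cross_corr * sds[0] * sds[1]
    return cov


def _simulate_states(growth: GrowthConfig, design: PanelDesign, rng):
    """Common core: coefficients, per-wave latent states, and retention flags.

    Returns (coeffs, ages (n, W), true latent values, states = latent +
    occasion residual, observed flags), all keyed/stacked per wave.
    """
    growth.validate()
    design.validate()
    n = design.n_persons
    procs = growth.processes
    coeffs = draw_growth_coefficients(growth, n, rng)
    base_age = _baseline_ages(design, rng)
    waves = np.asarray(design.wave_years, dtype=float)
    ages = base_age[:, None] + waves[None, :]

    rcov = _occasion_residual_cov(growth)
    rroot = np.linalg.cholesky(rcov + 1e-14 * np.eye(len(procs))) if np.any(rcov) else np.zeros_like(rcov)

    latent = np.empty((n, len(waves), len(procs)))
    states = np.empty_like(latent)
    for w in range(len(waves)):
        vals = latent_value_at_age(coeffs, ages[:, w], growth)
        eps = rng.standard_normal((n, len(procs))) @ rroot.T
        for j, p in enumerate(procs):
            latent[:, w, j] = vals[p]
            states[:, w, j] = vals[p] + eps[:, j]

    if design.mar_attrition_coef != 0.0 and "FNC" not in procs:
        raise ConfigError("MAR attrition requires an FNC process in the growth config")
    fnc_j = procs.index("FNC") if "FNC" in procs else None

    observed = np.ones((n, len(waves)), dtype=bool)
    for w in range(len(waves)):
        p_ret = np.full(n, design.retention[w])
        if design.mar_attrition_coef != 0.0 and w > 0:
            fnc = states[:, w, fnc_j]
            eta = np.log(p_ret / (1 - p_ret)) if design.retention[w] < 1 else np.full(n, 36.0)
            eta = eta - design.mar_attrition_coef * (fnc - fnc.mean())
            p_ret = 1.0 / (1.0 + np.exp(-eta))
        stay = rng.uniform(size=n) < p_ret
        observed[:, w] = stay if w == 0 else observed[:, w - 1] & stay

    return coeffs, ages, latent, states, observed


def _truth_table(growth, design, coeffs, ages, latent, observed) -> pd.DataFrame:
    n, W = ages.shape
    procs = growth.processes
    rows = {
        "pid": np.repeat(np.arange(n), W),
        "wave_year": np.tile(design.wave_labels, n),
        "age_years": ages.ravel(),
        "observed": observed.ravel(),
    }
    for j, p in enumerate(procs):
        rows[f"true_{p.lower()}"] = latent[:, :, j].ravel()
    truth = pd.DataFrame(rows)
    for j, name in enumerate(growth.latent_names):
        truth[name] = np.repeat(coeffs[:, j], W)
    return truth


def generate_score_panel(growth: GrowthConfig, design: PanelDesign):
    """Factor-score-level panel: latent trajectory + occasion residual.

    Returns ``(panel, truth)``: the panel has one row per retained
    person-wave with columns pid, wave_year, age_years and
    ``<proc>_score`` per process; the truth table has one row per
    person-wave with the noise-free latent values, coefficients and
    observed flags.
    """
    rng = np.random.default_rng(design.seed)
    coeffs, ages, latent, states, observed = _simulate_states(growth, design, rng)
    procs = growth.processes
    truth = _truth_table(growth, design, coeffs, ages, latent, observed)
    keep = observed.ravel()
    panel = truth.loc[keep, ["pid", "wave_year", "age_years"]].reset_index(drop=True)
    for j, p in enumerate(procs):
        panel[f"{p.lower()}_score"] = states[:, :, j].ravel()[keep]
    return panel, truth


def generate_item_panel(growth: GrowthConfig, meas: MeasurementConfig, design: PanelDesign):
    """Item-level panel: linear measurement of the occasion latent states.

    Continuous items are ``nu + loading * state + noise``; count items pass
    the same linear index through rounding and clipping to the item range.
    Returns ``(panel, truth)`` as in :func:`generate_score_panel`.
    """
    meas.validate()
    rng = np.random.default_rng(design.seed)
    coeffs, ages, latent, states, observed = _simulate_states(growth, design, rng)
    procs = list(growth.processes)
    truth = _truth_table(growth, design, coeffs, ages, latent, observed)
    keep = observed.ravel()
    panel = truth.loc[keep, ["pid", "wave_year", "age_years"]].reset_index(drop=True)
    n, W = ages.shape
    for item in meas.items:
        j = procs.index(item.process)
        noise = rng.standard_normal((n, W)) * item.residual_sd
        y = item.intercept + item.loading * states[:, :, j] + noise
        if item.output == "count":
            y = np.clip(np.rint(y), item.minimum, item.maximum)
        panel[item.label] = y.ravel()[keep]
    return panel, truth
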