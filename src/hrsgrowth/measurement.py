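"""Stage 1: longitudinal bivariate factor analysis and Bartlett scoring.

Items are first standardized against their first-wave (reference-wave)
means and SDs, then a two-process longitudinal CFA is fit across the three
waves under strong factorial invariance (item loadings and intercepts
equality-constrained across waves; latent means fixed to zero at the first
wave and free later; full latent covariance).  Occasion-level factor scores
are extracted per person-wave with Bartlett's weighted-least-squares
estimator using whatever indicators that person observed at that wave.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sem.model import SEMResults, StructuralModel
from .sem.structure import MomentStructure

__all__ = [
    "StandardizationRecord", "standardize_items", "build_lfa_structure",
    "LongitudinalFactorModel", "fit_bivariate_lfa", "bartlett_scores",
    "bartlett_score_block",
]


@dataclass
class StandardizationRecord:
    """Reference-wave item means/SDs, applied to every wave."""

    ref_wave: int
    stats: dict = field(default_factory=dict)   # item -> (mean, sd)

    def transform(self, panel: pd.DataFrame) -> pd.DataFrame:
        out = panel.copy()
        for item, (m, s) in self.stats.items():
            out[item] = (out[item] - m) / s
        return out

    def inverse(self, panel: pd.DataFrame) -> pd.DataFrame:
        out = panel.copy()
        for item, (m, s) in self.stats.items():
            out[item] = out[item] * s + m
        return out

    def to_dict(self) -> dict:
        return {"ref_wave": self.ref_wave,
                "stats": {k: list(v) for k, v in self.stats.items()}}


def standardize_items(panel: pd.DataFrame, items, ref_wave: int,
                      wave_col: str = "wave_year"):
    """Standardize item columns by their reference-wave mean and SD.

    Returns ``(standardized panel, StandardizationRecord)``.  After the
    transform the reference-wave columns have mean ~0 and SD ~1; later-wave
    means reflect raw longitudinal drift.
    """
    ref = panel.loc[panel[wave_col] == ref_wave]
    if ref.empty:
        raise ValueError(f"reference wave {ref_wave} not present in panel")
    record = StandardizationRecord(ref_wave=ref_wave)
    for item in items:
        m = float(ref[item].mean())
        s = float(ref[item].std(ddof=1))
        if not np.isfinite(s) or s <= 0:
            raise ValueError(f"item {item!r} has zero variance at wave {ref_wave}")
        record.stats[item] = (m, s)
    return record.transform(panel), record


def manifest_name(item: str, wave: int) -> str:
    return f"{item}_{wave}"


def build_lfa_structure(items_by_process: dict, waves, invariance: str = "strong",
                        markers: dict | None = None) -> MomentStructure:
    """Longitudinal two-process CFA structure over ``waves``.

    ``items_by_process`` maps process label -> item list; the first item of
    each process is the marker (loading fixed at 1) unless ``markers``
    overrides it.  ``invariance='strong'`` shares each item's loading and
    intercept across waves and frees latent means after the first wave;
    ``'configural'`` frees loadings/intercepts per wave with all latent
    means fixed at zero.
    """
    if invariance not in ("configural", "strong"):
        raise ValueError("invariance must be 'configural' or 'strong'")
    waves = list(waves)
    if len(waves) < 2:
        raise ValueError("longitudinal invariance needs at least 2 waves")
    procs = list(items_by_process)
    markers = markers or {p: items_by_process[p][0] for p in procs}
    items = [(p, it) for p in procs for it in items_by_process[p]]

    manifest = [manifest_name(it, w) for w in waves for _, it in items]
    latent = [f"{p}_{w}" for w in waves for p in procs]
    m, k = len(manifest), len(latent)

    lam = np.zeros((m, k), dtype=object)
    nu = np.empty(m, dtype=object)
    theta = np.zeros((m, m), dtype=object)
    positive = set()
    for wi, w in enumerate(waves):
        for ii, (p, it) in enumerate(items):
            r = wi * len(items) + ii
            c = latent.index(f"{p}_{w}")
            if it == markers[p]:
                lam[r, c] = 1.0
            else:
                lam[r, c] = f"load_{it}" if invariance == "strong" else f"load_{it}_{w}"
            nu[r] = f"int_{it}" if invariance == "strong" else f"int_{it}_{w}"
            resid = f"resid_{it}_{w}"
            theta[r, r] = resid
            positive.add(resid)

    alpha = np.empty(k, dtype=object)
    for wi, w in enumerate(waves):
        for p in procs:
            c = latent.index(f"{p}_{w}")
            if invariance == "strong" and wi > 0:
                alpha[c] = f"mean_{p}_{w}"
            else:
                alpha[c] = 0.0

    psi = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(i + 1):
            psi[i, j] = psi[j, i] = (f"var_{latent[i]}" if i == j
                                     else f"cov_{latent[i]}__{latent[j]}")

    structure = MomentStructure(manifest, latent, nu, lam, alpha, psi, theta,
                                psi_cholesky=True, positive=positive)
    start = {f"var_{ln}": 0.8 for ln in latent}
    for label in structure.param_names:
        if label.startswith("load_"):
            start[label] = 0.7
    structure.set_start(**start)
    return structure


class LongitudinalFactorModel:
    """Bivariate longitudinal CFA bound to a long-format item panel."""

    def __init__(self, panel: pd.DataFrame, items_cog, items_fnc,
                 id_col: str = "pid", wave_col: str = "wave_year",
                 age_col: str = "age_years", ref_wave: int | None = None,
                 invariance: str = "strong", standardize: bool = True):
        self.items_by_process = {"COG": list(items_cog), "FNC": list(items_fnc)}
        self.items = list(items_cog) + list(items_fnc)
        self.id_col, self.wave_col, self.age_col = id_col, wave_col, age_col
        self.waves = sorted(panel[wave_col].unique())
        self.ref_wave = ref_wave if ref_wave is not None else self.waves[0]
        self.invariance = invariance
        if standardize:
            panel, self.standardization = standardize_items(
                panel, self.items, self.ref_wave, wave_col=wave_col)
        else:
            self.standardization = None
        self.panel = panel
        self.structure = build_lfa_structure(self.items_by_process, self.waves,
                                             invariance=invariance)
        wide = panel.pivot_table(index=id_col, columns=wave_col,
                                 values=self.items, aggfunc="first")
        wide.columns = [manifest_name(item, wave) for item, wave in wide.columns]
        self.wide = wide.reindex(columns=self.structure.manifest_names)
        self._model = StructuralModel(self.structure, self.wide)

    def fit(self, **kwargs) -> SEMResults:
        res = self._model.fit(**kwargs)
        res.lfa = self
        return res

    # ------------------------------------------------------------------
    def wave_blocks(self, result: SEMResults):
        """Per-wave (items, nu, lam, theta) sub-blocks of the fitted matrices."""
        nu, lam, alpha, psi, theta = result.matrices()
        blocks = {}
        n_items = len(self.items)
        for wi, w in enumerate(self.waves):
            rows = slice(wi * n_items, (wi + 1) * n_items)
            cols = [self.structure.latent_names.index(f"{p}_{w}")
                    for p in self.items_by_process]
            blocks[w] = (nu[rows], lam[rows, :][:, cols], theta[rows, rows])
        return blocks


def fit_bivariate_lfa(panel: pd.DataFrame, items_cog, items_fnc,
                      **kwargs) -> SEMResults:
    """Convenience wrapper: build and fit the strong-invariance bivariate LFA."""
    lfa = LongitudinalFactorModel(panel, items_cog, items_fnc, **kwargs)
    return lfa.fit()


# ---------------------------------------------------------------------------
# Bartlett factor scores


def bartlett_score_block(y: np.ndarray, nu: np.ndarray, lam: np.ndarray,
                         theta: np.ndarray):
    """Bartlett WLS score for one observed vector: (L'T^-1 L)^-1 L'T^-1 (y-nu).

    Returns ``(score, error_cov)``; inputs are the observed-subset
    intercepts, loadings and (diagonal) residual covariance.
    """
    Tinv = np.linalg.inv(theta)
    M = lam.T @ Tinv @ lam
    Minv = np.linalg.inv(M)
    return Minv @ lam.T @ Tinv @ (y - nu), Minv


def bartlett_scores(result: SEMResults, lfa: LongitudinalFactorModel | None = None,
                    panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per person-wave Bartlett factor scores from a fitted LFA.

    Scoring is done per wave over that wave's two factors, using only the
    indicators the person observed; a factor with no observed indicator at
    a wave gets a missing score.  Returns a long FactorScorePanel with
    columns pid, wave_year, age_years, cog_score, fnc_score, pattern_id;
    per-pattern score-error covariances are attached as
    ``.attrs['error_cov']``.
    """
    if lfa is None:
        lfa = getattr(result, "lfa", None)
    if lfa is None:
        raise ValueError("pass the LongitudinalFactorModel the result came from")
    if not result.converged:
        warnings.warn("scoring from a non-converged fit")
    src = lfa.panel if panel is None else panel
    procs = list(lfa.items_by_process)
    blocks = lfa.wave_blocks(result)
    rows = []
    error_cov = {}
    for w in lfa.waves:
        nu_w, lam_w, theta_w = blocks[w]
        sub = src.loc[src[lfa.wave_col] == w]
        Y = sub[lfa.items].to_numpy(dtype=float)
        obs_mask = ~np.isnan(Y)
        key = obs_mask @ (1 << np.arange(len(lfa.items), dtype=object))
        for pat in np.unique(key):
            sel = key == pat
            obs = np.flatnonzero(obs_mask[np.flatnonzero(sel)[0]])
            if len(obs) == 0:
                continue
            # factors with at least one observed indicator
            fac = [j for j, p in enumerate(procs)
                   if np.any(lam_w[obs, j] != 0)]
            pattern_id = f"{w}:" + "".join("1" if i in obs else "0"
                                           for i in range(len(lfa.items)))
            L = lam_w[np.ix_(obs, fac)]
            T = theta_w[np.ix_(obs, obs)]
            scores, ecov = bartlett_score_block(
                Y[np.ix_(sel, obs)].T, nu_w[obs][:, None], L, T)
            error_cov[pattern_id] = (tuple(procs[j] for j in fac), ecov)
            block = pd.DataFrame({
                lfa.id_col: sub.loc[sel, lfa.id_col].to_numpy(),
                lfa.wave_col: w,
                lfa.age_col: sub.loc[sel, lfa.age_col].to_numpy(),
                "pattern_id": pattern_id,
            })
            for p in procs:
                col = f"{p.lower()}_score"
                if p in [procs[j] for j in fac]:
                    block[col] = scores[[procs[j] for j in fac].index(p)]
                else:
                    block[col] = np.nan
            rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    out = out.sort_values([lfa.id_col, lfa.wave_col]).reset_index(drop=True)
    out.attrs["error_cov"] = error_cov
    return out
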