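"""End-to-end two-stage analysis pipeline.

simulate (or ingest) -> screen -> standardize -> longitudinal factor
analysis -> Bartlett scores -> age bins -> rescale at 70/71 -> univariate
and bivariate trajectory fits -> comparison tables and reports.

Every artifact is written under an output directory together with a JSON
manifest (seed, case counts, per-stage timing, convergence ledger) from
which the run can be regenerated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .config import (default_bivariate_growth, default_design,
                     default_measurement, load_config)
from .measurement import LongitudinalFactorModel, bartlett_scores
from .simulate import generate_item_panel
from .trajectory import (KNOT_CANDIDATES, TrajectorySpec, assign_age_bins,
                         compare_models, comparison_text, cumulative_change,
                         fit_bivariate_trajectory, fit_trajectory,
                         fit_univariate_trajectories, rescale_at_bin)

__all__ = ["PipelineConfig", "run_pipeline", "screen_input", "bivariate_report"]

log = logging.getLogger("hrsgrowth")

ITEMS_COG = ["numeracy", "fluency", "serial7", "recall"]
ITEMS_FNC = ["mobility", "adl", "iadl"]


@dataclass
class PipelineConfig:
    input_csv: str | None = None          # None -> simulate from config
    config_file: str | None = None        # YAML/JSON generator config
    ref_wave: int = 2010
    age_range: tuple = (50.0, 85.0)
    knot_candidates: tuple = KNOT_CANDIDATES
    model_set: tuple = ("intercept_only", "linear", "spline")
    bivariate_set: tuple = (("spline", "linear"), ("linear", "linear"))
    out_dir: str = "hrsgrowth_run"
    seed: int = 0
    n_persons: int = 3000
    alpha: float = 0.005
    items_cog: tuple = tuple(ITEMS_COG)
    items_fnc: tuple = tuple(ITEMS_FNC)

    def validate(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.model_set:
            raise ValueError("model_set must be non-empty")


def screen_input(panel: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Apply inclusion screening: age range at first assessment, plus any
    optional boolean exclusion flags present in the data.

    Persons whose first observed assessment age falls outside the configured
    range are removed entirely.  Columns named ``exclude_*`` (e.g. a
    pre-existing dementia or recent-depression flag supplied by the caller)
    drop the flagged persons; no attempt is made to derive such flags.
    """
    if "age_years" not in panel.columns:
        raise ValueError("panel must contain an age_years column")
    lo, hi = config.age_range
    first = panel.sort_values("wave_year").groupby("pid")["age_years"].first()
    keep_ids = first[(first >= lo) & (first <= hi)].index
    out = panel[panel.pid.isin(keep_ids)]
    n_age = panel.pid.nunique() - len(keep_ids)
    if n_age:
        log.info("screen: removed %d persons outside ages %g-%g at first assessment",
                 n_age, lo, hi)
    for col in [c for c in out.columns if c.startswith("exclude_")]:
        flagged = out.loc[out[col].astype(bool), "pid"].unique()
        out = out[~out.pid.isin(flagged)]
        log.info("screen: removed %d persons flagged by %s", len(flagged), col)
    if out.empty:
        raise ValueError("screening removed every row of the input panel")
    return out


def _stars(p: float, alpha: float) -> str:
    return "*" if p < alpha else ""


def bivariate_report(result, alpha: float = 0.005) -> str:
    """Estimates of the bivariate trajectory model in a Table-3-like layout:
    latent means/variances/residuals with robust SEs and Wald tests, then
    latent correlations with delta-method tests."""
    params = result.params
    se = result.se_robust
    names = result.model.structure.latent_names
    lines = [f"{'Parameter':<46s}{'Estimate':>9s}{'S.E.':>8s}{'Z':>9s}{'p':>11s}"]

    def row(label, est, s):
        z = est / s if s > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z))
        lines.append(f"{label:<46s}{est:>9.3f}{s:>8.3f}{z:>9.2f}{p:>11.3g} "
                     f"{_stars(p, alpha)}")

    lines.append("Means")
    for nm in names:
        row(f"  {nm}", params[f"mean_{nm}"], se[f"mean_{nm}"])
    lines.append("Variances")
    for nm in names:
        row(f"  {nm}", params[f"var_{nm}"], se[f"var_{nm}"])
    for lbl in [p for p in params.index if p.startswith("resid_")]:
        row(f"  {lbl}", params[lbl], se[lbl])

    lines.append("Correlations (standardized covariances)")
    cov = result.cov_robust
    if cov is None:
        lines.append("  (no robust covariance available)")
    else:
        idx = {p: i for i, p in enumerate(params.index)}
        for i, ni in enumerate(names):
            for j in range(i):
                nj = names[j]
                lab = f"cov_{ni}__{nj}"
                a, b, c = params[lab], params[f"var_{ni}"], params[f"var_{nj}"]
                r = a / np.sqrt(b * c)
                g = np.zeros(len(params))
                g[idx[lab]] = 1.0 / np.sqrt(b * c)
                g[idx[f"var_{ni}"]] = -r / (2 * b)
                g[idx[f"var_{nj}"]] = -r / (2 * c)
                s = float(np.sqrt(g @ cov @ g))
                row(f"  {ni} ~ {nj}", r, s)
    for proc in ("COG", "FNC"):
        pre, post = f"mean_{proc}_s1", f"mean_{proc}_s2"
        if pre in params.index:
            ch = cumulative_change((params[pre], params[post]))
            lines.append(f"cumulative change {proc}: ages 50-70 = {ch['50_70']:+.2f} SD, "
                         f"ages 70-85 = {ch['70_85']:+.2f} SD")
    return "\n".join(lines)


def _write(path: Path, text: str):
    path.write_text(text)
    log.info("wrote %s", path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full two-stage analysis; returns the artifact manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in dataclasses.asdict(config).items()},
                "stages": {}, "convergence": {}, "counts": {}}
    t_all = time.time()
    stage = "input"
    try:
        # ---- input ----------------------------------------------------
        t0 = time.time()
        if config.input_csv:
            panel = pd.read_csv(config.input_csv)
            truth = None
        else:
            if config.config_file:
                growth, meas, design = load_config(config.config_file)
                design = dataclasses.replace(design, seed=config.seed)
            else:
                growth = default_bivariate_growth()
                meas = default_measurement()
                design = default_design(config.n_persons, seed=config.seed)
            panel, truth = generate_item_panel(growth, meas, design)
            panel.to_csv(out / "item_panel.csv", index=False,
                         float_format="%.10g")
            truth.to_csv(out / "truth.csv", index=False, float_format="%.10g")
            (out / "seed.json").write_text(json.dumps({"seed": config.seed}))
        manifest["counts"]["input_rows"] = int(len(panel))
        manifest["stages"]["input"] = round(time.time() - t0, 3)

        stage = "screen"
        t0 = time.time()
        panel = screen_input(panel, config)
        manifest["counts"]["screened_rows"] = int(len(panel))
        manifest["counts"]["persons"] = int(panel.pid.nunique())
        manifest["stages"]["screen"] = round(time.time() - t0, 3)

        # ---- stage 1: measurement -------------------------------------
        stage = "lfa"
        t0 = time.time()
        lfa = LongitudinalFactorModel(panel, list(config.items_cog),
                                      list(config.items_fnc),
                                      ref_wave=config.ref_wave)
        std_panel = lfa.panel
        std_panel.to_csv(out / "standardized_panel.csv", index=False,
                         float_format="%.10g")
        _write(out / "standardization.json",
               json.dumps(lfa.standardization.to_dict(), indent=1))
        lfa_res = lfa.fit()
        manifest["convergence"]["lfa_strong_invariance"] = bool(lfa_res.converged)
        _write(out / "lfa_fit.txt", lfa_res.summary(alpha=config.alpha))
        _write(out / "lfa_fit.json", lfa_res.to_json())
        manifest["stages"]["lfa"] = round(time.time() - t0, 3)

        stage = "scores"
        t0 = time.time()
        scores = bartlett_scores(lfa_res, lfa)
        scores.to_csv(out / "factor_scores.csv", index=False,
                      float_format="%.10g")
        manifest["counts"]["score_rows"] = int(len(scores))
        manifest["stages"]["scores"] = round(time.time() - t0, 3)

        # ---- stage 2: trajectories ------------------------------------
        stage = "bins"
        t0 = time.time()
        mat = assign_age_bins(scores)
        manifest["counts"]["dropped_outside_age_bins"] = mat.n_dropped_age
        manifest["counts"]["averaged_bin_collisions"] = mat.n_averaged
        mat = rescale_at_bin(mat, 70)
        mat.data.to_csv(out / "age_bin_matrix.csv", float_format="%.10g")
        manifest["stages"]["bins"] = round(time.time() - t0, 3)

        stage = "univariate"
        t0 = time.time()
        reports = []
        for proc in ("COG", "FNC"):
            specs = []
            for kind in config.model_set:
                if kind == "spline":
                    specs += [TrajectorySpec({proc: "spline"}, knot_bin=kb)
                              for kb in config.knot_candidates]
                else:
                    specs.append(TrajectorySpec({proc: kind}))
            fits = fit_univariate_trajectories(mat, proc, specs=specs)
            for label, r in fits.items():
                manifest["convergence"][label] = bool(r.converged)
            tab = compare_models(fits)
            reports.append(f"== {proc} ==\n" + comparison_text(tab))
        _write(out / "univariate_comparison.txt", "\n\n".join(reports))
        manifest["stages"]["univariate"] = round(time.time() - t0, 3)

        stage = "bivariate"
        t0 = time.time()
        fits = {}
        for cog_kind, fnc_kind in config.bivariate_set:
            spec = TrajectorySpec({"COG": cog_kind, "FNC": fnc_kind}, knot_bin=70)
            fits[spec.label()] = fit_bivariate_trajectory(mat, spec)
        for label, r in fits.items():
            manifest["convergence"][label] = bool(r.converged)
        tab = compare_models(fits)
        best_label = tab.attrs["best"]
        manifest["best_bivariate"] = best_label
        text = comparison_text(tab)
        if best_label:
            text += "\n\n== best bivariate model: " + best_label + " ==\n"
            text += bivariate_report(fits[best_label], alpha=config.alpha)
            _write(out / "bivariate_fit.json", fits[best_label].to_json())
        _write(out / "bivariate_comparison.txt", text)
        manifest["stages"]["bivariate"] = round(time.time() - t0, 3)
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        _write(out / "manifest.json", json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    _write(out / "manifest.json", json.dumps(manifest, indent=1))
    return manifest
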