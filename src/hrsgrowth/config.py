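"""Configuration objects for the synthetic HRS-style panel generator.

Three dataclasses describe, respectively, the latent bivariate growth
process (:class:`GrowthConfig`), the item-level measurement model
(:class:`MeasurementConfig`) and the accelerated-longitudinal panel design
(:class:`PanelDesign`).  The default values encode the published bivariate
spline(COG)+linear(FNC) growth solution for the Health and Retirement Study
2010/2012/2016 waves, so that panels drawn from the defaults have a known
ground truth matching the real-data analysis scale (factor scores
standardized at age 70, slopes per decade).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "GrowthConfig",
    "MeasurementConfig",
    "ItemConfig",
    "PanelDesign",
    "default_bivariate_growth",
    "default_univariate_growth",
    "default_measurement",
    "default_design",
    "dump_default_config",
    "load_config",
]

#: latent labels of the full bivariate spline(COG) + linear(FNC) process
BIVARIATE_LATENTS = ("COG_i", "COG_s1", "COG_s2", "FNC_i", "FNC_s")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class GrowthConfig:
    """Latent growth process: means, covariance and occasion residuals.

    ``latent_names`` follow the convention ``<PROC>_i`` (intercept at the
    age-70 centering point), ``<PROC>_s1``/``<PROC>_s2`` (pre-/post-knot
    spline slopes per decade) and ``<PROC>_s`` (single linear slope per
    decade).  Units are factor-score SDs at age 70.
    """

    latent_names: tuple = BIVARIATE_LATENTS
    latent_means: tuple = (0.031, -0.047, -0.230, 0.115, 0.229)
    latent_sds: tuple = (0.8815, 0.3768, 0.6427, 0.8769, 0.3873)
    latent_corr: tuple = (
        (1.000, 0.445, -0.564, -0.300, -0.310),
        (0.445, 1.000, 0.154, -0.090, -0.489),
        (-0.564, 0.154, 1.000, 0.153, 0.196),
        (-0.300, -0.090, 0.153, 1.000, 0.429),
        (-0.310, -0.489, 0.196, 0.429, 1.000),
    )
    #: per-process occasion residual SD, keyed by process label
    residual_sds: dict = field(default_factory=lambda: {"COG": 0.5595, "FNC": 0.6892})
    #: within-occasion cross-process residual correlation
    residual_cross_corr: float = 0.007
    knot_age: float = 70.0

    # -- derived -----------------------------------------------------------
    @property
    def processes(self) -> tuple:
        seen = []
        for name in self.latent_names:
            proc = name.split("_")[0]
            if proc not in seen:
                seen.append(proc)
        return tuple(seen)

    def corr_matrix(self) -> np.ndarray:
        return np.asarray(self.latent_corr, dtype=float)

    def cov_matrix(self) -> np.ndarray:
        s = np.asarray(self.latent_sds, dtype=float)
        return self.corr_matrix() * np.outer(s, s)

    def validate(self) -> None:
        k = len(self.latent_names)
        if len(self.latent_means) != k or len(self.latent_sds) != k:
            raise ConfigError("latent_means/latent_sds length must match latent_names")
        R = self.corr_matrix()
        if R.shape != (k, k):
            raise ConfigError("latent_corr shape must match latent_names")
        if not np.allclose(R, R.T):
            raise ConfigError("latent_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ConfigError("latent_corr must have unit diagonal")
        if np.min(np.linalg.eigvalsh(R)) < -1e-10:
            raise ConfigError("latent_corr is not positive semidefinite")
        if np.any(np.asarray(self.latent_sds) < 0):
            raise ConfigError("latent_sds must be nonnegative")
        for proc in self.processes:
            if proc not in self.residual_sds:
                raise ConfigError(f"missing residual SD for process {proc}")
            if self.residual_sds[proc] < 0:
                raise ConfigError("residual_sds must be nonnegative")
        if abs(self.residual_cross_corr) > 1:
            raise ConfigError("|residual_cross_corr| must be <= 1")

    def slope_names(self, process: str) -> tuple:
        """Latent slope labels for a process in (pre, post) or (linear,) form."""
        names = [n for n in self.latent_names if n.startswith(process + "_s")]
        return tuple(names)


@dataclass
class ItemConfig:
    """One observed indicator: linear in its process's latent value."""

    label: str
    process: str
    loading: float
    intercept: float
    residual_sd: float
    #: 'continuous' or 'count' (rounded and clipped to [minimum, maximum])
    output: str = "continuous"
    minimum: float = 0.0
    maximum: float = np.inf
    reference: bool = False


@dataclass
class MeasurementConfig:
    items: tuple = ()

    def validate(self) -> None:
        procs = {}
        for it in self.items:
            if it.residual_sd <= 0:
                raise ConfigError(f"residual SD must be > 0 for item {it.label}")
            if it.output not in ("continuous", "count"):
                raise ConfigError(f"unknown output mapping for item {it.label}")
            if it.output == "count" and not it.minimum < it.maximum:
                raise ConfigError(f"count bounds invalid for item {it.label}")
            procs.setdefault(it.process, []).append(it)
        for proc, items in procs.items():
            if sum(it.reference for it in items) != 1:
                raise ConfigError(f"process {proc} needs exactly one reference item")

    def labels(self, process: str | None = None) -> tuple:
        return tuple(it.label for it in self.items if process in (None, it.process))


@dataclass
class PanelDesign:
    """Accelerated longitudinal design: waves 2010 (+0), 2012 (+2), 2016 (+6)."""

    n_persons: int = 3000
    wave_years: tuple = (0, 2, 6)
    baseline_year: int = 2010
    baseline_age_mean: float = 64.9
    baseline_age_sd: float = 9.6
    #: analysis age range (observations outside are dropped downstream)
    age_range: tuple = (50.0, 85.0)
    #: truncation bounds for generated baseline ages
    baseline_age_range: tuple = (50.0, 83.0)
    #: report age in whole years at assessment, as HRS does
    integer_ages: bool = True
    #: per-wave retention probability conditional on presence at previous wave
    retention: tuple = (1.0, 0.916, 0.821)
    #: log-odds of dropout per unit of current (centered) FNC; 0 = MCAR
    mar_attrition_coef: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ConfigError("n_persons must be >= 1")
        w = np.asarray(self.wave_years, dtype=float)
        if w[0] != 0 or np.any(np.diff(w) <= 0):
            raise ConfigError("wave_years must be strictly increasing and start at 0")
        if len(self.retention) != len(self.wave_years):
            raise ConfigError("retention must have one entry per wave")
        if np.any(np.asarray(self.retention) <= 0) or np.any(np.asarray(self.retention) > 1):
            raise ConfigError("retention must lie in (0, 1]")
        lo, hi = self.baseline_age_range
        if not lo < hi:
            raise ConfigError("baseline_age_range must be increasing")

    @property
    def wave_labels(self) -> tuple:
        return tuple(self.baseline_year + int(w) for w in self.wave_years)


# ---------------------------------------------------------------------------
# defaults


def default_bivariate_growth() -> GrowthConfig:
    """Bivariate spline(COG)+linear(FNC) growth solution (published fit)."""
    cfg = GrowthConfig()
    cfg.validate()
    return cfg


_UNIVARIATE = {
    # means (intercept, pre-knot, post-knot), SDs = sqrt of printed variances
    "COG": {
        "means": (0.0, -0.027, -0.187),
        "sds": (np.sqrt(0.521), np.sqrt(0.086), np.sqrt(0.284)),
        "corr": ((1.0, 0.445, -0.564), (0.445, 1.0, 0.154), (-0.564, 0.154, 1.0)),
        "resid_sd": 0.5595,
    },
    "FNC": {
        "means": (0.0, 0.112, 0.452),
        "sds": (np.sqrt(0.755), np.sqrt(0.096), np.sqrt(1.147)),
        "corr": ((1.0, 0.429, 0.429), (0.429, 1.0, 0.154), (0.429, 0.154, 1.0)),
        "resid_sd": 0.6892,
    },
}


def default_univariate_growth(process: str) -> GrowthConfig:
    """Univariate spline growth configuration for ``COG`` or ``FNC``.

    Means and variances come from the published univariate spline fits;
    within-process correlations and occasion residuals are not printed for
    those fits and default to the bivariate-solution values.
    """
    if process not in _UNIVARIATE:
        raise ConfigError(f"unknown process {process!r}")
    u = _UNIVARIATE[process]
    cfg = GrowthConfig(
        latent_names=(f"{process}_i", f"{process}_s1", f"{process}_s2"),
        latent_means=tuple(u["means"]),
        latent_sds=tuple(float(s) for s in u["sds"]),
        latent_corr=u["corr"],
        residual_sds={process: u["resid_sd"]},
    )
    cfg.validate()
    return cfg


def default_measurement() -> MeasurementConfig:
    """Seven HRS-style indicators in raw-like metrics.

    Loadings/residuals are calibrated so that the standardized loadings of
    the fitted longitudinal factor model reproduce the published pattern
    (numeracy highest ~.85 and recall lowest ~.445 for cognition; ADL ~.82
    and IADL lowest ~.578 for functional limitation), and intercepts/scales
    roughly match the published wave-2010 descriptives.  Count items are
    rounded and clipped, which gives the functional-limitation items their
    characteristic positive skew (floor at zero).
    """
    # baseline latent SD is ~1.04 under the default growth config at the
    # observed age distribution; loadings below fold that in.
    items = (
        ItemConfig("numeracy", "COG", 35.0, 510.0, 21.0, "continuous", reference=True),
        ItemConfig("fluency", "COG", 4.7, 17.4, 5.1, "count", 0.0, 60.0),
        ItemConfig("serial7", "COG", 1.05, 3.4, 1.45, "count", 0.0, 5.0),
        ItemConfig("recall", "COG", 1.55, 10.1, 3.0, "count", 0.0, 20.0),
        ItemConfig("mobility", "FNC", 2.05, 1.9, 1.55, "count", 0.0, 11.0, reference=True),
        ItemConfig("adl", "FNC", 1.2, -0.9, 0.55, "count", 0.0, 6.0),
        ItemConfig("iadl", "FNC", 0.55, -0.65, 0.5, "count", 0.0, 5.0),
    )
    cfg = MeasurementConfig(items=items)
    cfg.validate()
    return cfg


def default_design(n_persons: int = 3000, seed: int = 0) -> PanelDesign:
    d = PanelDesign(n_persons=n_persons, seed=seed)
    d.validate()
    return d


# ---------------------------------------------------------------------------
# serialisation


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if obj == np.inf:
        return "inf"
    return obj


def dump_default_config() -> str:
    """Render the full default configuration (growth, measurement, design) as YAML."""
    cfg = {
        "growth": _to_jsonable(default_bivariate_growth()),
        "measurement": _to_jsonable(default_measurement()),
        "design": _to_jsonable(default_design()),
    }
    return yaml.safe_dump(cfg, sort_keys=False)


def _tupled(d: dict) -> dict:
    return {
        k: tuple(tuple(r) for r in v) if k == "latent_corr" else (tuple(v) if isinstance(v, list) else v)
        for k, v in d.items()
    }


def load_config(path: str):
    """Load a YAML/JSON config file with sections growth, measurement, design."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) if not str(path).endswith(".json") else json.load(fh)
    growth = GrowthConfig(**_tupled(raw["growth"])) if "growth" in raw else default_bivariate_growth()
    if "measurement" in raw:
        items = []
        for it in raw["measurement"]["items"]:
            it = dict(it)
            if it.get("maximum") == "inf":
                it["maximum"] = np.inf
            items.append(ItemConfig(**it))
        meas = MeasurementConfig(items=tuple(items))
    else:
        meas = default_measurement()
    design = PanelDesign(**_tupled(raw["design"])) if "design" in raw else default_design()
    growth.validate()
    meas.validate()
    design.validate()
    return growth, meas, design
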