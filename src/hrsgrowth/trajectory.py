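"""Age-binned latent trajectory models (stage 2).

Factor scores from an accelerated longitudinal panel are restructured into
2-year age bins (50/51 ... 84/85), giving a person x (18 bins x process)
sparsely observed matrix.  Latent growth models — intercept-only, linear, or
piecewise-linear spline with a knot bin — are then fit to the bins by FIML,
with time coded in decades centered at age 70 (the 70/71 bin is the zero
point).  The bivariate model couples the two processes through a full latent
covariance matrix plus a single within-bin cross-process residual
covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sem.likelihood import independence_fit, saturated_loglik
from .sem.model import SEMResults, StructuralModel
from .sem.structure import MomentStructure

__all__ = [
    "AgeBinMatrix", "TrajectorySpec", "assign_age_bins", "rescale_at_bin",
    "build_trajectory_structure", "fit_trajectory", "fit_univariate_trajectories",
    "fit_bivariate_trajectory", "compare_models", "cumulative_change",
    "BIN_LOWERS", "KNOT_CANDIDATES",
]

BIN_LOWERS = tuple(range(50, 85, 2))          # 18 bins: 50/51 ... 84/85
KNOT_CANDIDATES = (60, 64, 70, 74)
CENTER_AGE = 70.0


def time_code(bin_lower) -> np.ndarray:
    """Decades from the centering age, using the lower bin edge."""
    return (np.asarray(bin_lower, dtype=float) - CENTER_AGE) / 10.0


def bin_column(process: str, lower: int) -> str:
    return f"{process.lower()}_b{lower}"


@dataclass
class AgeBinMatrix:
    """Person x (bin x process) wide matrix of factor scores."""

    data: pd.DataFrame            # index pid, 18 columns per process
    processes: tuple
    n_dropped_age: int = 0
    n_averaged: int = 0
    rescaled_at: int | None = None
    scale_record: dict = field(default_factory=dict)

    def columns(self, process: str) -> list:
        return [bin_column(process, b) for b in BIN_LOWERS]

    def counts(self) -> pd.Series:
        return self.data.notna().sum()

    @property
    def n_bins(self) -> int:
        return len(BIN_LOWERS)


def assign_age_bins(scores: pd.DataFrame, processes=("COG", "FNC"),
                    id_col: str = "pid", age_col: str = "age_years") -> AgeBinMatrix:
    """Place person-wave factor scores into 2-year age bins.

    ``floor(age)`` maps into its bin; ages below 50 or above 85 (i.e. floor
    > 85) are dropped and counted.  Two occasions of one person landing in
    the same bin are averaged, with the number of averaged occasions logged.
    """
    procs = tuple(processes)
    score_cols = {p: f"{p.lower()}_score" for p in procs}
    df = scores.copy()
    df.attrs = {}  # score-error metadata would break pandas concat
    fl = np.floor(df[age_col].to_numpy())
    ok = (fl >= 50) & (fl <= 85)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} observations outside ages 50-85")
    df = df.loc[ok]
    lower = (50 + 2 * ((np.floor(df[age_col].to_numpy()) - 50) // 2)).astype(int)
    df = df.assign(_bin=lower)

    dup = df.duplicated(subset=[id_col, "_bin"]).sum()
    if dup:
        warnings.warn(f"averaged {int(dup)} occasions falling into an already "
                      "occupied age bin")
    pieces = {}
    for p in procs:
        wide = df.pivot_table(index=id_col, columns="_bin",
                              values=score_cols[p], aggfunc="mean")
        wide = wide.reindex(columns=list(BIN_LOWERS))
        wide.columns = [bin_column(p, b) for b in BIN_LOWERS]
        pieces[p] = wide
    data = pd.concat(pieces.values(), axis=1)
    return AgeBinMatrix(data=data, processes=procs,
                        n_dropped_age=n_dropped, n_averaged=int(dup))


def rescale_at_bin(matrix: AgeBinMatrix, bin_lower: int = 70) -> AgeBinMatrix:
    """Standardize each process's bin columns by the target bin's mean and SD.

    A pure linear rescaling of the manifest variables: model fit statistics
    (chi-square, TLI, RMSEA) are unchanged, while means/slopes are expressed
    in target-bin SD units.
    """
    data = matrix.data.copy()
    record = {}
    for p in matrix.processes:
        col = data[bin_column(p, bin_lower)]
        if col.notna().sum() < 2:
            raise ValueError(f"target bin {bin_lower}/{bin_lower+1} has fewer "
                             f"than 2 observations for process {p}")
        m, s = float(col.mean()), float(col.std(ddof=1))
        record[p] = (m, s)
        cols = matrix.columns(p)
        data[cols] = (data[cols] - m) / s
    return AgeBinMatrix(data=data, processes=matrix.processes,
                        n_dropped_age=matrix.n_dropped_age,
                        n_averaged=matrix.n_averaged,
                        rescaled_at=bin_lower, scale_record=record)


# ---------------------------------------------------------------------------


@dataclass
class TrajectorySpec:
    """Which processes to model and how each one's change is parameterized."""

    parameterization: dict       # process -> intercept_only | linear | spline
    knot_bin: int = 70           # lower edge of the knot bin (spline only)

    def __post_init__(self):
        for p, kind in self.parameterization.items():
            if kind not in ("intercept_only", "linear", "spline"):
                raise ValueError(f"unknown parameterization {kind!r} for {p}")
        if any(k == "spline" for k in self.parameterization.values()):
            if self.knot_bin not in KNOT_CANDIDATES:
                raise ValueError(f"knot bin must be one of {KNOT_CANDIDATES}")

    @property
    def processes(self) -> tuple:
        return tuple(self.parameterization)

    def latent_names(self, process: str) -> list:
        kind = self.parameterization[process]
        if kind == "intercept_only":
            return [f"{process}_i"]
        if kind == "linear":
            return [f"{process}_i", f"{process}_s"]
        return [f"{process}_i", f"{process}_s1", f"{process}_s2"]

    def label(self) -> str:
        bits = []
        for p, kind in self.parameterization.items():
            txt = {"intercept_only": "intercept-only", "linear": "linear",
                   "spline": f"spline KP={self.knot_bin}/{self.knot_bin+1}"}[kind]
            bits.append(f"{p} ({txt})")
        return " + ".join(bits)


def build_trajectory_structure(spec: TrajectorySpec) -> MomentStructure:
    """Latent growth moment structure on the 18-bin manifest grid.

    Intercept loadings are 1; a linear slope loads the decade time code
    ``s``; spline slopes load ``min(s - s_knot, 0)`` and ``max(s - s_knot,
    0)`` around the knot bin.  Manifest intercepts are fixed at 0 with free
    latent means; the latent covariance is fully free; residual variances
    are homogeneous within process, plus (bivariate) one within-bin
    cross-process residual covariance shared across all bins.
    """
    procs = spec.processes
    manifest, latent = [], []
    for p in procs:
        manifest += [bin_column(p, b) for b in BIN_LOWERS]
        latent += spec.latent_names(p)
    m, k = len(manifest), len(latent)
    s = time_code(BIN_LOWERS)
    s_knot = float(time_code(spec.knot_bin))

    lam = np.zeros((m, k), dtype=object)
    for pi, p in enumerate(procs):
        rows = slice(pi * len(BIN_LOWERS), (pi + 1) * len(BIN_LOWERS))
        names = spec.latent_names(p)
        cols = [latent.index(nm) for nm in names]
        lam[rows, cols[0]] = 1.0
        kind = spec.parameterization[p]
        if kind == "linear":
            lam[rows, cols[1]] = s
        elif kind == "spline":
            lam[rows, cols[1]] = np.minimum(s - s_knot, 0.0)
            lam[rows, cols[2]] = np.maximum(s - s_knot, 0.0)

    nu = np.zeros(m, dtype=object)
    alpha = np.array([f"mean_{nm}" for nm in latent], dtype=object)

    psi = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(i + 1):
            psi[i, j] = psi[j, i] = (f"var_{latent[i]}" if i == j
                                     else f"cov_{latent[i]}__{latent[j]}")

    theta = np.zeros((m, m), dtype=object)
    positive = set()
    for pi, p in enumerate(procs):
        label = f"resid_{p}"
        positive.add(label)
        for b in range(len(BIN_LOWERS)):
            theta[pi * len(BIN_LOWERS) + b, pi * len(BIN_LOWERS) + b] = label
    if len(procs) == 2:
        for b in range(len(BIN_LOWERS)):
            i, j = b, len(BIN_LOWERS) + b
            theta[i, j] = theta[j, i] = "resid_cov"

    structure = MomentStructure(manifest, latent, nu, lam, alpha, psi, theta,
                                psi_cholesky=True, positive=positive)
    start = {}
    for nm in latent:
        start[f"var_{nm}"] = 0.6 if nm.endswith("_i") else 0.2
    for p in procs:
        start[f"resid_{p}"] = 0.4
    structure.set_start(**start)
    return structure


# ---------------------------------------------------------------------------


def _shared_references(matrix: AgeBinMatrix, processes):
    """Saturated and baseline log-likelihoods shared by models on one table."""
    cols = sum((matrix.columns(p) for p in processes), [])
    from .sem.likelihood import MissingPatternData
    data = MissingPatternData.from_dataframe(matrix.data[cols])
    ll_sat, _, _ = saturated_loglik(data)
    baseline = independence_fit(data)
    return ll_sat, baseline


def fit_trajectory(matrix: AgeBinMatrix, spec: TrajectorySpec,
                   compute_indices: bool = True, references=None,
                   compute_se: bool = True) -> SEMResults:
    """Fit one trajectory specification to the bin matrix."""
    structure = build_trajectory_structure(spec)
    model = StructuralModel(structure, matrix.data[structure.manifest_names])
    saturated = baseline = None
    if compute_indices:
        if references is None:
            references = _shared_references(matrix, spec.processes)
        saturated, baseline = references
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence surfaced via the flag
        res = model.fit(compute_indices=compute_indices, compute_se=compute_se,
                        saturated=saturated, baseline=baseline)
    res.spec = spec
    return res


def fit_univariate_trajectories(matrix: AgeBinMatrix, process: str,
                                specs=None, compute_se: bool = True) -> dict:
    """Fit the univariate candidate set to one process.

    Default candidates: intercept-only, linear, and splines at each knot
    bin.  Returns an ordered ``{label: SEMResults}``; convergence is
    reported per model, never silently accepted.
    """
    if specs is None:
        specs = [TrajectorySpec({process: "intercept_only"}),
                 TrajectorySpec({process: "linear"})]
        specs += [TrajectorySpec({process: "spline"}, knot_bin=kb)
                  for kb in KNOT_CANDIDATES]
    references = _shared_references(matrix, (process,))
    out = {}
    for spec in specs:
        res = fit_trajectory(matrix, spec, references=references,
                             compute_se=compute_se)
        out[spec.label()] = res
    return out


def fit_bivariate_trajectory(matrix: AgeBinMatrix, spec: TrajectorySpec | None = None,
                             compute_indices: bool = True, references=None,
                             compute_se: bool = True) -> SEMResults:
    """Fit a bivariate latent trajectory model (default spline COG + linear FNC)."""
    if spec is None:
        spec = TrajectorySpec({"COG": "spline", "FNC": "linear"}, knot_bin=70)
    if len(spec.processes) != 2:
        raise ValueError("bivariate model requires two processes")
    return fit_trajectory(matrix, spec, compute_indices=compute_indices,
                          references=references, compute_se=compute_se)


def compare_models(results: dict) -> pd.DataFrame:
    """Comparison table for models fit to the same data.

    Rows carry chi2(df), TLI, RMSEA [95% CI], AIC and the convergence flag;
    nested pairs (sorted by decreasing df) get delta-chi2 / delta-df; the
    best model is the converged one with the lowest AIC.
    """
    items = list(results.items())
    ref = items[0][1]
    for _, r in items[1:]:
        same = (r.n_cases == ref.n_cases
                and r.model.structure.manifest_names == ref.model.structure.manifest_names
                and (r.saturated_llf is None or ref.saturated_llf is None
                     or np.isclose(r.saturated_llf, ref.saturated_llf)))
        if not same:
            raise ValueError("compare_models requires fits on identical data")
    rows = []
    for label, r in items:
        rows.append({
            "model": label, "chi2": r.chi2, "df": r.df,
            "tli": r.tli, "rmsea": r.rmsea,
            "rmsea_lo": None if r.rmsea_ci is None else r.rmsea_ci[0],
            "rmsea_hi": None if r.rmsea_ci is None else r.rmsea_ci[1],
            "aic": r.aic, "converged": r.converged,
        })
    tab = pd.DataFrame(rows).sort_values("df", ascending=False).reset_index(drop=True)
    tab["delta_chi2"] = -tab["chi2"].diff()
    tab["delta_df"] = -tab["df"].diff()
    conv = tab[tab.converged]
    tab.attrs["best"] = None if conv.empty else conv.loc[conv.aic.idxmin(), "model"]
    return tab


def comparison_text(tab: pd.DataFrame) -> str:
    lines = [f"{'Model':<55s}{'Chi2(df)':>14s}{'TLI':>7s}{'RMSEA [95%CI]':>22s}"
             f"{'AIC':>12s}  conv"]
    for _, r in tab.iterrows():
        chi = "" if pd.isna(r.chi2) else f"{r.chi2:.0f} ({int(r.df)})"
        rm = ("" if pd.isna(r.rmsea)
              else f"{r.rmsea:.3f} [{r.rmsea_lo:.3f}, {r.rmsea_hi:.3f}]")
        tli = "" if pd.isna(r.tli) else f"{r.tli:.3f}"
        lines.append(f"{r.model:<55s}{chi:>14s}{tli:>7s}{rm:>22s}"
                     f"{r.aic:>12,.0f}  {'yes' if r.converged else 'NO'}")
    if tab.attrs.get("best"):
        lines.append(f"best (lowest AIC among converged): {tab.attrs['best']}")
    return "\n".join(lines)


def cumulative_change(result_or_slopes, process: str | None = None) -> dict:
    """Cumulative mean change over ages 50-70 and 70-85 for a spline process.

    Per-decade slope means are multiplied by the 2.0 decades spanning ages
    50-70 and the 1.5 decades spanning 70-85.  Accepts a fitted spline
    ``SEMResults`` (with ``process``) or a ``(pre, post)`` slope pair.
    """
    if isinstance(result_or_slopes, SEMResults):
        pre = result_or_slopes.params[f"mean_{process}_s1"]
        post = result_or_slopes.params[f"mean_{process}_s2"]
    else:
        pre, post = result_or_slopes
    return {"50_70": 2.0 * float(pre), "70_85": 1.5 * float(post)}
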