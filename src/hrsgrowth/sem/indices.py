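"""Model fit indices: TLI, RMSEA with noncentral-chi-square CI, AIC.

RMSEA uses ``n = number of analysis cases`` and a 95% confidence interval,
matching the reporting convention of the analysis this package reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["fit_indices", "FitIndices", "rmsea_ci"]


@dataclass
class FitIndices:
    tli: float
    rmsea: float
    rmsea_ci: tuple
    tli_capped: bool = False


def _ncp_at(prob: float, chi2: float, df: int) -> float:
    """Noncentrality lambda with ncx2.cdf(chi2, df, lambda) = prob."""
    if stats.chi2.cdf(chi2, df) < prob:  # even lambda = 0 is too large
        return 0.0
    hi = max(chi2 - df, 1.0)
    while stats.ncx2.cdf(chi2, df, hi) > prob:
        hi *= 2.0
        if hi > 1e8:
            return hi
    return optimize.brentq(lambda l: stats.ncx2.cdf(chi2, df, l) - prob, 0.0, hi, xtol=1e-8)


def rmsea_ci(chi2: float, df: int, n: int, level: float = 0.95) -> tuple:
    lo = _ncp_at(0.5 + level / 2, chi2, df)
    hi = _ncp_at(0.5 - level / 2, chi2, df)
    return (np.sqrt(lo / (df * n)), np.sqrt(hi / (df * n)))


def fit_indices(chi2: float, df: int, chi2_baseline: float, df_baseline: int,
                n_cases: int, ci_level: float = 0.95) -> FitIndices:
    if df <= 0 or df_baseline <= 0:
        raise ValueError("df and df_baseline must be positive")
    rb = chi2_baseline / df_baseline
    rm = chi2 / df
    capped = False
    if rb <= 1.0:
        warnings.warn("baseline fits no worse than saturated per df; TLI capped at 1")
        tli, capped = 1.0, True
    else:
        tli = (rb - rm) / (rb - 1.0)
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * n_cases)))
    ci = rmsea_ci(chi2, df, n_cases, ci_level)
    return FitIndices(tli=float(tli), rmsea=rmsea, rmsea_ci=ci, tli_capped=capped)
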