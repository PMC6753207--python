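"""Pleiotropy and robustness diagnostics for an IVW analysis.

MR-Egger regression relaxes the IVW model by fitting an intercept: with
instruments oriented so every exposure effect is non-negative, a weighted
regression beta_Y = a + b * beta_X (weights se(beta_Y)^-2) estimates the
average pleiotropic effect ``a`` (directional pleiotropy if non-zero)
and a pleiotropy-adjusted causal slope ``b``. Cochran's Q quantifies
heterogeneity of the per-SNP ratios; leave-one-out re-estimation reveals
single-instrument dominance; funnel data (ratio vs. inverse SE) expose
the small-study-style asymmetry that accompanies directional pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .harmonize import HarmonizedInstrument
from .mr import MrResult, RatioEstimate, cochran_q, ivw_pool, wald_ratio

__all__ = [
    "EggerResult",
    "LooResult",
    "egger_regression",
    "egger_arrays",
    "cochran_q",
    "leave_one_out",
    "funnel_data",
]


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    intercept_pvalue: float
    slope: float
    slope_se: float
    slope_pvalue: float
    n_snps: int


@dataclass(frozen=True)
class LooResult:
    omitted_rsid: str
    theta_ivw_without: float
    se_without: float
    odds_ratio_without: float


def egger_arrays(
    beta_x: np.ndarray, beta_y: np.ndarray, se_y: np.ndarray
) -> tuple[float, float, float, float, float, float]:
    """Weighted Egger regression kernel on effect arrays.

    Instruments are re-oriented to non-negative beta_x (beta_y flipped in
    tandem), then beta_y is regressed on beta_x with an intercept and
    weights se_y^-2. Standard errors use the estimated residual scale
    (weighted RSS / (J - 2)) and inference is Student t with J - 2 df.

    Returns (intercept, intercept_se, intercept_p, slope, slope_se, slope_p).
    """
    beta_x = np.asarray(beta_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    n = beta_x.size
    if n < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger needs at least 3 instruments, got {n}"
        )
    if np.any(beta_x == 0):
        raise ZeroDivisionError("beta_exposure of 0 must be excluded before MR-Egger")

    sign = np.where(beta_x < 0, -1.0, 1.0)
    x = beta_x * sign
    y = beta_y * sign
    w = se_y ** -2.0

    # closed-form weighted least squares with intercept
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar

    resid = y - intercept - slope * x
    df = n - 2
    sigma2 = (w * resid**2).sum() / df
    slope_var = sigma2 / sxx
    intercept_var = sigma2 * (1.0 / sw + xbar**2 / sxx)

    slope_se = float(np.sqrt(slope_var))
    intercept_se = float(np.sqrt(intercept_var))
    slope_p = float(2.0 * stats.t.sf(abs(slope / slope_se), df=df))
    intercept_p = float(2.0 * stats.t.sf(abs(intercept / intercept_se), df=df))
    return float(intercept), intercept_se, intercept_p, float(slope), slope_se, slope_p


def egger_regression(harmonized: Sequence[HarmonizedInstrument]) -> EggerResult:
    """MR-Egger intercept test for directional pleiotropy.

    A non-zero intercept indicates pleiotropic effects on the outcome
    that differ on average from zero; if it is not significantly
    different from 0 there is no evidence against the no-directional-
    pleiotropy null.
    """
    bx = np.array([h.beta_exposure for h in harmonized])
    by = np.array([h.beta_outcome for h in harmonized])
    sy = np.array([h.se_outcome for h in harmonized])
    a, a_se, a_p, b, b_se, b_p = egger_arrays(bx, by, sy)
    return EggerResult(
        intercept=a,
        intercept_se=a_se,
        intercept_pvalue=a_p,
        slope=b,
        slope_se=b_se,
        slope_pvalue=b_p,
        n_snps=len(harmonized),
    )


def leave_one_out(harmonized: Sequence[HarmonizedInstrument]) -> list[LooResult]:
    """Re-estimate IVW J times, omitting each instrument in turn."""
    if len(harmonized) < 3:
        raise InsufficientInstrumentsError(
            f"leave-one-out needs at least 3 instruments, got {len(harmonized)}"
        )
    ratios = [wald_ratio(h) for h in harmonized]
    results = []
    for i, omitted in enumerate(ratios):
        reduced = ratios[:i] + ratios[i + 1 :]
        res = ivw_pool(reduced, group=f"without {omitted.rsid}")
        results.append(
            LooResult(
                omitted_rsid=omitted.rsid,
                theta_ivw_without=res.theta_ivw,
                se_without=res.se_ivw,
                odds_ratio_without=res.odds_ratio,
            )
        )
    return results


def funnel_data(
    ratios: Sequence[RatioEstimate], theta_ivw: float
) -> pd.DataFrame:
    """Per-SNP ratio vs. inverse standard error, for funnel plotting.

    One row per instrument with the Wald ratio and its inverse SE
    (instrument strength); the pooled estimate is carried in the
    ``theta_ivw`` column as the vertical reference. Asymmetry about that
    line — a correlation between effect size and strength — flags
    possible directional pleiotropy. Rendering is left to the caller.
    """
    if not ratios:
        raise InsufficientInstrumentsError("funnel data needs at least 1 ratio")
    return pd.DataFrame(
        {
            "rsid": [r.rsid for r in ratios],
            "theta": [r.theta for r in ratios],
            "inverse_se": [r.variance ** -0.5 for r in ratios],
            "theta_ivw": theta_ivw,
        }
    )
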