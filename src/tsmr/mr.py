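"""Per-SNP Wald ratios and the fixed-effect inverse-variance weighted estimate.

For instrument j with exposure effect beta_Xj and outcome effect beta_Yj,
the Wald ratio

    theta_j = beta_Yj / beta_Xj

estimates the causal log-odds effect of the exposure on the outcome. Its
first-order variance, se(beta_Yj)^2 / beta_Xj^2, treats the exposure
effect as known (the NOME assumption, appropriate when instruments come
from very large discovery GWAS). The pooled fixed-effect IVW estimate is
the inverse-variance weighted mean of the ratios,

    theta_IVW = sum_j w_j theta_j / sum_j w_j,   w_j = 1 / var(theta_j),

algebraically identical to the slope of a zero-intercept weighted
least-squares regression of beta_Y on beta_X with weights se(beta_Y)^-2,
with standard error (sum_j w_j)^(-1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InsufficientInstrumentsError
from .harmonize import HarmonizedInstrument

#: 97.5th percentile of the standard normal; full precision so that
#: confidence limits rounded to 2 decimals match meta-analysis tables.
Z_975 = 1.959964

GROUPINGS = ("per-cancer", "smoking", "non-smoking", "all")
SMOKING_GROUP = "Smoking-related cancers (all)"
NON_SMOKING_GROUP = "Non-smoking-related cancers (all)"
ALL_GROUP = "All cancers"


@dataclass(frozen=True)
class RatioEstimate:
    """One instrument's Wald ratio with its first-order variance."""

    rsid: str
    theta: float
    variance: float

    def __post_init__(self) -> None:
        if not (self.variance > 0):
            raise ValueError(f"{self.rsid}: ratio variance must be > 0")

    @property
    def weight(self) -> float:
        return 1.0 / self.variance


@dataclass(frozen=True)
class MrResult:
    """Pooled causal estimate for one instrument group, on both scales."""

    group: str
    n_snps: int
    theta_ivw: float
    se_ivw: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    q_statistic: float
    q_pvalue: float


def wald_ratio(h: HarmonizedInstrument) -> RatioEstimate:
    """Per-SNP causal estimate: outcome effect over exposure effect."""
    if h.beta_exposure == 0:
        raise ZeroDivisionError(f"{h.rsid}: beta_exposure is 0; Wald ratio undefined")
    theta = h.beta_outcome / h.beta_exposure
    variance = (h.se_outcome / h.beta_exposure) ** 2
    return RatioEstimate(rsid=h.rsid, theta=theta, variance=variance)


def ivw_arrays(theta: np.ndarray, weight: np.ndarray) -> tuple[float, float]:
    """Weighted-mean kernel: pooled estimate and its fixed-effect SE."""
    wsum = float(np.sum(weight))
    est = float(np.sum(weight * theta) / wsum)
    return est, wsum ** -0.5


def cochran_q(
    ratios: Sequence[RatioEstimate], theta_ivw: float
) -> tuple[float, float]:
    """Heterogeneity of per-SNP ratios around the pooled estimate.

    Q = sum_j w_j (theta_j - theta_IVW)^2, referred to a chi-square
    distribution with J - 1 degrees of freedom.
    """
    if len(ratios) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 ratios")
    theta = np.array([r.theta for r in ratios])
    w = np.array([r.weight for r in ratios])
    q = float(np.sum(w * (theta - theta_ivw) ** 2))
    pvalue = float(stats.chi2.sf(q, df=len(ratios) - 1))
    return q, pvalue


def ivw_pool(ratios: Sequence[RatioEstimate], group: str = "") -> MrResult:
    """Fixed-effect inverse-variance weighted pooling of Wald ratios.

    The p-value is the two-sided standard-normal tail of theta/se; the
    odds ratio and its 95% CI exponentiate theta_IVW +/- 1.959964 se.
    A single instrument cannot be pooled — report its Wald ratio directly.
    """
    if len(ratios) < 2:
        raise InsufficientInstrumentsError(
            f"{group or 'group'}: IVW pooling needs at least 2 instruments, got {len(ratios)}"
        )
    theta = np.array([r.theta for r in ratios])
    w = np.array([r.weight for r in ratios])
    est, se = ivw_arrays(theta, w)
    z = est / se
    pvalue = float(2.0 * stats.norm.sf(abs(z)))
    q, q_p = cochran_q(ratios, est)
    return MrResult(
        group=group,
        n_snps=len(ratios),
        theta_ivw=est,
        se_ivw=se,
        odds_ratio=math.exp(est),
        ci_low=math.exp(est - Z_975 * se),
        ci_high=math.exp(est + Z_975 * se),
        pvalue=pvalue,
        q_statistic=q,
        q_pvalue=q_p,
    )


def group_instruments(
    harmonized: Iterable[HarmonizedInstrument], grouping: str
) -> dict[str, list[HarmonizedInstrument]]:
    """Partition instruments into the requested analysis groups.

    Instruments keep one row per cancer they instrument: an rsid shared
    between two cancers contributes twice to a pooled group.
    """
    if grouping not in GROUPINGS:
        raise ConfigurationError(
            f"unknown grouping {grouping!r}; expected one of {GROUPINGS}"
        )
    groups: dict[str, list[HarmonizedInstrument]] = {}
    for h in harmonized:
        if grouping == "per-cancer":
            key = h.cancer_type
        elif grouping == "smoking":
            if not h.smoking_related:
                continue
            key = SMOKING_GROUP
        elif grouping == "non-smoking":
            if h.smoking_related:
                continue
            key = NON_SMOKING_GROUP
        else:
            key = ALL_GROUP
        groups.setdefault(key, []).append(h)
    return groups


def pool_groups(
    harmonized: Sequence[HarmonizedInstrument],
    grouping: str,
    dedupe: bool = False,
) -> list[MrResult]:
    """One IVW result per analysis group.

    ``dedupe=True`` keeps only the first occurrence of each rsid within a
    group (the default retains cross-cancer duplicates as distinct rows).
    Groups with fewer than two instruments are skipped — a single
    instrument's Wald ratio is available via :func:`wald_ratio`.
    """
    results = []
    for key, members in group_instruments(harmonized, grouping).items():
        if dedupe:
            seen: set[str] = set()
            members = [h for h in members if not (h.rsid in seen or seen.add(h.rsid))]
        if len(members) < 2:
            continue
        results.append(ivw_pool([wald_ratio(h) for h in members], group=key))
    return results
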