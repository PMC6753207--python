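"""Bayesian false-discovery assessment of MR results.

A small p-value alone does not make an association noteworthy: the
posterior probability that a reported effect is a false discovery also
depends on how plausible a true effect was a priori and on the study's
power. Two standard constructions are provided:

* **FPRP** (false-positive report probability): combines the observed
  significance level alpha, the power to attain it under an alternative
  effect, and the prior probability pi1 that the null is false,

      FPRP = alpha * (1 - pi1) / (alpha * (1 - pi1) + power * pi1).

* **BFDP** (Bayesian false-discovery probability): an approximate Bayes
  factor against the null from the estimate and its SE, with a normal
  prior of variance W on the effect under the alternative.

Both are reported over a grid of priors, irrespective of the frequentist
significance of the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .mr import MrResult

#: Prior probabilities that the null is false, matching the reporting
#: convention BFDR_50% ... BFDR_0.1%.
DEFAULT_PRIORS = (0.5, 0.1, 0.01, 0.001)

#: Default prior variance of the effect under the alternative for BFDP:
#: 95% prior mass on odds ratios between 1/1.5 and 1.5.
DEFAULT_W = (np.log(1.5) / stats.norm.isf(0.025)) ** 2


@dataclass(frozen=True)
class BfdrResult:
    group: str
    priors: tuple[float, ...]
    posterior_fdr: tuple[float, ...]
    method: str

    def __post_init__(self) -> None:
        if any(not (0.0 <= v <= 1.0) for v in self.posterior_fdr):
            raise ValueError("posterior FDR values must lie in [0, 1]")


def _check_prior(prior_true: float) -> None:
    if not (0.0 < prior_true < 1.0):
        raise ConfigurationError(
            f"prior probability of a true effect must be in (0, 1), got {prior_true}"
        )


def two_sided_power(theta: float, se: float, alpha: float) -> float:
    """Probability of a two-sided p-value <= alpha when the effect is theta."""
    z_alpha = stats.norm.isf(alpha / 2.0)
    mu = theta / se
    return float(stats.norm.sf(z_alpha - mu) + stats.norm.cdf(-z_alpha - mu))


def fprp(
    pvalue: float,
    theta: float,
    se: float,
    prior_true: float,
    alpha_level: float | None = None,
) -> float:
    """False-positive report probability of one result.

    By default the significance level alpha is the observed p-value
    itself and the alternative effect is the observed point estimate, so
    each result gets its own posterior. ``alpha_level`` overrides alpha;
    power is computed from normal tails.
    """
    _check_prior(prior_true)
    if se <= 0:
        raise ConfigurationError(f"se must be > 0, got {se}")
    alpha = pvalue if alpha_level is None else alpha_level
    power = two_sided_power(theta, se, alpha)
    pi0 = 1.0 - prior_true
    return float(alpha * pi0 / (alpha * pi0 + power * prior_true))


def bfdp(
    theta: float,
    se: float,
    prior_true: float,
    prior_variance_w: float = DEFAULT_W,
) -> float:
    """Bayesian false-discovery probability via an approximate Bayes factor.

    With V = se^2 and z = theta/se, the Bayes factor for the null is

        BF = sqrt((V + W) / V) * exp(-z^2 W / (2 V (V + W))) * ... (in V units)

    i.e. the ratio of the marginal likelihoods of the estimate under the
    null and under a N(0, W) prior on the effect. The posterior null
    probability combines BF with the prior odds of the null.
    """
    _check_prior(prior_true)
    if prior_variance_w <= 0:
        raise ConfigurationError(f"prior variance W must be > 0, got {prior_variance_w}")
    if se <= 0:
        raise ConfigurationError(f"se must be > 0, got {se}")
    v = se**2
    w = prior_variance_w
    z = theta / se
    log_bf = 0.5 * np.log((v + w) / v) - (z**2) * w / (2.0 * (v + w))
    prior_odds_null = (1.0 - prior_true) / prior_true
    bf_po = np.exp(log_bf) * prior_odds_null
    return float(bf_po / (bf_po + 1.0))


def bfdr_table(
    results: Sequence[MrResult],
    priors: Sequence[float] = DEFAULT_PRIORS,
    method: str = "fprp",
    prior_variance_w: float = DEFAULT_W,
) -> list[BfdrResult]:
    """Posterior false-discovery grid for every group result.

    Computed for all results regardless of significance. Values are
    probabilities in [0, 1]; percentage formatting belongs to the
    reporting layer.
    """
    if method not in ("fprp", "bfdp"):
        raise ConfigurationError(f"unknown BFDR method {method!r}")
    out = []
    for res in results:
        if method == "fprp":
            vals = tuple(
                fprp(res.pvalue, res.theta_ivw, res.se_ivw, p) for p in priors
            )
        else:
            vals = tuple(
                bfdp(res.theta_ivw, res.se_ivw, p, prior_variance_w) for p in priors
            )
        out.append(
            BfdrResult(group=res.group, priors=tuple(priors), posterior_fdr=vals, method=method)
        )
    return out
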