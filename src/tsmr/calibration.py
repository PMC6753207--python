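"""Monte-Carlo calibration studies for the estimators.

Each study repeatedly draws synthetic two-sample replicates from a
scenario and summarizes how an estimator behaves across them: bias and
confidence-interval coverage for IVW, type-I error and intercept
recovery for the MR-Egger pleiotropy test, and rejection-rate
calibration for Cochran's Q. These run on raw effect arrays (no table
plumbing) so thousands of replicates finish in seconds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .mr import Z_975, ivw_arrays
from .sensitivity import egger_arrays
from .simulate import SyntheticScenario, draw_effect_arrays


def _replicate_rng(scn: SyntheticScenario, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(scn.seed if seed is None else seed)


def ivw_recovery_study(
    scn: SyntheticScenario, n_replicates: int = 1000, seed: int | None = None
) -> dict[str, float]:
    """Bias and 95% CI coverage of the IVW estimator over replicates.

    Returns the mean estimate, absolute bias, the Monte-Carlo standard
    error of that mean, and the fraction of replicates whose 95% CI
    covers the true effect.
    """
    rng = _replicate_rng(scn, seed)
    estimates = np.empty(n_replicates)
    covered = np.empty(n_replicates, dtype=bool)
    for i in range(n_replicates):
        eff = draw_effect_arrays(scn, rng)
        theta = eff["beta_y"] / eff["beta_x"]
        w = (eff["beta_x"] / eff["se_y"]) ** 2
        est, se = ivw_arrays(theta, w)
        estimates[i] = est
        covered[i] = abs(est - scn.theta_true) <= Z_975 * se
    mean = float(estimates.mean())
    return {
        "mean_theta": mean,
        "bias": mean - scn.theta_true,
        "mc_se": float(estimates.std(ddof=1) / np.sqrt(n_replicates)),
        "coverage": float(covered.mean()),
        "n_replicates": n_replicates,
    }


def egger_intercept_study(
    scn: SyntheticScenario,
    n_replicates: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Behaviour of the MR-Egger intercept test over replicates.

    Reports the rejection rate of the intercept test at ``alpha`` (the
    type-I error under balanced pleiotropy) and the mean estimated
    intercept with its Monte-Carlo SE (which recovers the mean
    pleiotropic effect under directional pleiotropy).
    """
    rng = _replicate_rng(scn, seed)
    intercepts = np.empty(n_replicates)
    rejected = np.empty(n_replicates, dtype=bool)
    for i in range(n_replicates):
        eff = draw_effect_arrays(scn, rng)
        a, _, a_p, *_ = egger_arrays(eff["beta_x"], eff["beta_y"], eff["se_y"])
        intercepts[i] = a
        rejected[i] = a_p < alpha
    return {
        "rejection_rate": float(rejected.mean()),
        "mean_intercept": float(intercepts.mean()),
        "mc_se": float(intercepts.std(ddof=1) / np.sqrt(n_replicates)),
        "n_replicates": n_replicates,
    }


def q_calibration_study(
    scn: SyntheticScenario,
    n_replicates: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Rejection rate of Cochran's Q under a homogeneous causal effect.

    With no pleiotropy and NOME, per-SNP ratios deviate from the pooled
    estimate only through outcome sampling noise, so Q is chi-square
    with J - 1 df and the test should reject at the nominal rate.
    """
    rng = _replicate_rng(scn, seed)
    rejected = np.empty(n_replicates, dtype=bool)
    for i in range(n_replicates):
        eff = draw_effect_arrays(scn, rng)
        theta = eff["beta_y"] / eff["beta_x"]
        w = (eff["beta_x"] / eff["se_y"]) ** 2
        est, _ = ivw_arrays(theta, w)
        q = float(np.sum(w * (theta - est) ** 2))
        p = stats.chi2.sf(q, df=scn.n_snps - 1)
        rejected[i] = p < alpha
    return {
        "rejection_rate": float(rejected.mean()),
        "n_replicates": n_replicates,
    }
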