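"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the data a summary-level MR analysis consumes: J
independent instruments with exposure log-odds effects beta_Xj (drawn
from a zero-centred normal, magnitude-floored so no ratio degenerates),
and outcome effects

    beta_Yj = theta_true * beta_Xj(true) + alpha_j + noise(se_y),

where alpha_j is a per-SNP pleiotropic intercept: zero (``none``),
zero-mean normal (``balanced``) or normal with non-zero mean
(``directional``). Pleiotropic intercepts act in the orientation where
the effect allele raises exposure risk — the orientation in which the
Egger intercept is interpretable — so recoding an allele flips the
variant's exposure, outcome and pleiotropic effects together. Under the default NOME setting the observed exposure
effects equal the true ones, matching the first-order weights that
ignore exposure uncertainty. Companion block-diagonal LD matrices and
proxy tables exercise the pruning and proxy-substitution stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .harmonize import HarmonizedInstrument
from .io import (
    InstrumentTable,
    LdMatrix,
    ProxyCandidate,
    ProxyTable,
    SnpAssociation,
)

#: Default seed used in documentation examples.
DEFAULT_SEED = 20190919

PLEIOTROPY_MODES = ("none", "balanced", "directional")

#: Exposure betas below this magnitude are pushed out to it, keeping
#: Wald ratios well defined.
BETA_X_FLOOR = 0.01

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"),
                 ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one two-sample summary-statistics draw.

    ``se_x`` and ``se_y`` are the reported standard errors of the
    exposure and outcome effects (log-odds scale); defaults reflect
    large discovery GWAS for the exposure and a ~50k-sample case-control
    meta-analysis for the outcome. ``nome`` (no measurement error in the
    exposure) makes the observed exposure betas equal the true ones.
    """

    n_snps: int = 50
    theta_true: float = 0.0
    beta_x_scale: float = 0.1
    se_x: float = 0.01
    se_y: float = 0.015
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    nome: bool = True
    seed: int = DEFAULT_SEED
    cancer_type: str = "synthetic"
    smoking_related: bool = False
    rsid_start: int = 1  # first rsid number; offsets keep multi-trait rsids disjoint

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError(f"n_snps must be >= 1, got {self.n_snps}")
        for name in ("beta_x_scale", "se_x", "se_y"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ConfigurationError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}, "
                f"got {self.pleiotropy_mode!r}"
            )
        if self.pleiotropy_mode == "balanced" and self.pleiotropy_mean != 0.0:
            raise ConfigurationError("balanced pleiotropy requires pleiotropy_mean = 0")


def draw_effect_arrays(
    scn: SyntheticScenario, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Raw effect arrays for one replicate (the fast path for simulation studies).

    Returns true and observed exposure betas, outcome betas, pleiotropic
    intercepts, and the per-SNP SE arrays.
    """
    if rng is None:
        rng = np.random.default_rng(scn.seed)
    j = scn.n_snps
    bx_true = rng.normal(0.0, scn.beta_x_scale, size=j)
    sign = np.where(bx_true < 0, -1.0, 1.0)
    bx_true = sign * np.maximum(np.abs(bx_true), BETA_X_FLOOR)

    if scn.nome:
        bx_obs = bx_true.copy()
    else:
        bx_obs = bx_true + rng.normal(0.0, scn.se_x, size=j)

    if scn.pleiotropy_mode == "none":
        alpha = np.zeros(j)
    else:
        # drawn in the exposure-raising orientation, then expressed in the
        # reported allele orientation
        alpha = sign * rng.normal(scn.pleiotropy_mean, scn.pleiotropy_sd, size=j)

    by = scn.theta_true * bx_true + alpha + rng.normal(0.0, scn.se_y, size=j)
    return {
        "beta_x_true": bx_true,
        "beta_x": bx_obs,
        "beta_y": by,
        "alpha": alpha,
        "se_x": np.full(j, scn.se_x),
        "se_y": np.full(j, scn.se_y),
    }


def _rsids(n: int, start: int = 1) -> list[str]:
    return [f"rs{i:06d}" for i in range(start, start + n)]


def simulate_two_sample(
    scn: SyntheticScenario,
) -> tuple[InstrumentTable, dict[str, SnpAssociation]]:
    """One synthetic exposure instrument table and matching outcome collection.

    Alleles are random A/C/G/T pairs shared between the two tables (a
    random half of the outcome rows report the swapped orientation, so
    harmonization has real work to do); rsids run rs000001, rs000002, ...
    Fully reproducible from the scenario seed.
    """
    rng = np.random.default_rng(scn.seed)
    eff = draw_effect_arrays(scn, rng)
    j = scn.n_snps
    rsids = _rsids(j, start=scn.rsid_start)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=j)
    swap_outcome = rng.random(j) < 0.5

    p_x = 2.0 * stats.norm.sf(np.abs(eff["beta_x"]) / scn.se_x)
    p_y = 2.0 * stats.norm.sf(np.abs(eff["beta_y"]) / scn.se_y)

    exposure_records = []
    outcome = {}
    for i in range(j):
        ea, oa = _ALLELE_PAIRS[pair_idx[i]]
        chrom = str(i % 22 + 1)
        pos = 1_000_000 + 10_000 * i
        exposure_records.append(
            SnpAssociation(
                rsid=rsids[i],
                chromosome=chrom,
                position=pos,
                effect_allele=ea,
                other_allele=oa,
                beta=float(eff["beta_x"][i]),
                se=scn.se_x,
                pvalue=float(p_x[i]),
            )
        )
        if swap_outcome[i]:
            out_ea, out_oa, out_beta = oa, ea, -eff["beta_y"][i]
        else:
            out_ea, out_oa, out_beta = ea, oa, eff["beta_y"][i]
        outcome[rsids[i]] = SnpAssociation(
            rsid=rsids[i],
            chromosome=chrom,
            position=pos,
            effect_allele=out_ea,
            other_allele=out_oa,
            beta=float(out_beta),
            se=scn.se_y,
            pvalue=float(p_y[i]),
        )
    table = InstrumentTable(
        cancer_type=scn.cancer_type,
        smoking_related=scn.smoking_related,
        records=exposure_records,
    )
    return table, outcome


def simulate_harmonized(
    scn: SyntheticScenario, rng: np.random.Generator | None = None
) -> list[HarmonizedInstrument]:
    """Directly build a harmonized instrument set from one replicate.

    Convenience for simulation studies that exercise the estimators
    without the table/file plumbing.
    """
    eff = draw_effect_arrays(scn, rng)
    return [
        HarmonizedInstrument(
            rsid=f"rs{scn.rsid_start + i:06d}",
            effect_allele="A",
            other_allele="G",
            beta_exposure=float(eff["beta_x"][i]),
            se_exposure=scn.se_x,
            beta_outcome=float(eff["beta_y"][i]),
            se_outcome=scn.se_y,
            cancer_type=scn.cancer_type,
            smoking_related=scn.smoking_related,
        )
        for i in range(scn.n_snps)
    ]


def simulate_ld_fixture(
    n_loci: int,
    snps_per_locus: int,
    within_r2: float,
    seed: int = DEFAULT_SEED,
    proxy_r2: float = 0.95,
) -> tuple[LdMatrix, ProxyTable]:
    """Block-diagonal LD structure with one designated proxy pair per locus.

    Within a locus every SNP pair has r^2 = ``within_r2``; across loci
    r^2 = 0. The last SNP of each locus is treated as "missing from the
    outcome data" and mapped to the locus's first SNP as its proxy at
    r^2 = ``proxy_r2``, with a consistent allele bijection.
    """
    if not (0.0 <= within_r2 <= 1.0):
        raise ConfigurationError(f"within_r2 must be in [0, 1], got {within_r2}")
    rng = np.random.default_rng(seed)
    n = n_loci * snps_per_locus
    rsids = _rsids(n)
    r2 = np.zeros((n, n))
    for locus in range(n_loci):
        lo, hi = locus * snps_per_locus, (locus + 1) * snps_per_locus
        r2[lo:hi, lo:hi] = within_r2
    np.fill_diagonal(r2, 1.0)
    ld = LdMatrix(rsids=tuple(rsids), r2=r2)

    proxies = []
    if snps_per_locus >= 2:
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=(n_loci, 2))
        for locus in range(n_loci):
            target = rsids[(locus + 1) * snps_per_locus - 1]
            proxy = rsids[locus * snps_per_locus]
            t_ea, t_oa = _ALLELE_PAIRS[pair_idx[locus, 0]]
            p_ea, p_oa = _ALLELE_PAIRS[pair_idx[locus, 1]]
            proxies.append(
                ProxyCandidate(
                    target_rsid=target,
                    proxy_rsid=proxy,
                    r2=proxy_r2,
                    allele_map={t_ea: p_ea, t_oa: p_oa},
                )
            )
    return ld, ProxyTable(rows=tuple(proxies))


#: Published group sizes and pooled odds ratios used for end-to-end
#: smoke tests: lung 18 / leukemia 38 / breast 109 / smoking-related 68 /
#: non-smoking-related 246 / all 314.
PAPER_SCALE_GROUPS = (
    ("Lung cancer", True, 18, 0.91),
    ("Leukemia", False, 38, 0.98),
    ("Breast cancer", False, 109, 0.94),
    ("Smoking-related cancers (all)", True, 68, 0.95),
    ("Non-smoking-related cancers (all)", False, 246, 0.98),
    ("All cancers", False, 314, 0.98),
)


def paper_scale_scenario(seed: int = DEFAULT_SEED) -> list[SyntheticScenario]:
    """Preset scenarios sized like the published analysis groups.

    Each preset's true causal effect is the log of the corresponding
    pooled odds ratio, so a full pipeline run on these presets should
    recover estimates near the published values. rsid ranges are
    disjoint across presets, so the six exposure tables can share one
    outcome table.
    """
    out = []
    start = 1
    for i, (label, smoking, j, or_) in enumerate(PAPER_SCALE_GROUPS):
        out.append(
            SyntheticScenario(
                n_snps=j,
                theta_true=math.log(or_),
                cancer_type=label,
                smoking_related=smoking,
                seed=seed + i,
                rsid_start=start,
            )
        )
        start += j
    return out
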