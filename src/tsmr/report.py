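"""Result-table formatting: the reporting layer owns all rounding.

Odds ratios and confidence limits are printed to 2 decimals, Egger
intercepts to 3, Q statistics to 2; p-values get 3 significant figures,
switching to scientific notation (2.7E-4 style) below 1e-3. BFDR values
are percentages at 2 decimals. Estimates themselves are never rounded
before this layer.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .bfdr import BfdrResult
from .mr import MrResult
from .sensitivity import EggerResult

RESULT_COLUMNS = [
    "Cancer type",
    "No. of SNPs",
    "Odds ratio",
    "Lower confidence limit",
    "Upper confidence limit",
    "P-value",
]

SENSITIVITY_COLUMNS = [
    "Cancer type",
    "No. of SNPs",
    "Intercept",
    "Standard error",
    "P-value",
    "Q",
    "Q P-value",
]


def format_pvalue(p: float) -> str:
    """3 significant figures; scientific (2.7E-4 style) below 1e-3."""
    if p != p:  # NaN
        return "NA"
    if p >= 1e-3:
        return f"{p:.3g}"
    mantissa_exp = f"{p:.1E}"  # e.g. 2.7E-04
    mantissa, exp = mantissa_exp.split("E")
    return f"{mantissa}E{int(exp)}"


def _bfdr_label(prior: float) -> str:
    pct = prior * 100
    return f"BFDR_{pct:g}%"


def results_frame(
    results: Sequence[MrResult],
    bfdr: Sequence[BfdrResult] | None = None,
    rounded: bool = True,
) -> pd.DataFrame:
    """Main results table (one row per analysis group), optionally with BFDR columns."""
    bfdr_by_group: Mapping[str, BfdrResult] = (
        {b.group: b for b in bfdr} if bfdr else {}
    )
    rows = []
    for res in results:
        row = {
            "Cancer type": res.group,
            "No. of SNPs": res.n_snps,
            "Odds ratio": round(res.odds_ratio, 2) if rounded else res.odds_ratio,
            "Lower confidence limit": round(res.ci_low, 2) if rounded else res.ci_low,
            "Upper confidence limit": round(res.ci_high, 2) if rounded else res.ci_high,
            "P-value": format_pvalue(res.pvalue) if rounded else res.pvalue,
        }
        b = bfdr_by_group.get(res.group)
        if b is not None:
            for prior, value in zip(b.priors, b.posterior_fdr):
                pct = value * 100
                row[_bfdr_label(prior)] = round(pct, 2) if rounded else pct
        rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_frame(
    eggers: Mapping[str, EggerResult],
    mr_results: Sequence[MrResult],
    rounded: bool = True,
) -> pd.DataFrame:
    """Pleiotropy/heterogeneity table: Egger intercept test plus Cochran's Q."""
    q_by_group = {r.group: r for r in mr_results}
    rows = []
    for group, egg in eggers.items():
        mr = q_by_group.get(group)
        rows.append(
            {
                "Cancer type": group,
                "No. of SNPs": egg.n_snps,
                "Intercept": round(egg.intercept, 3) if rounded else egg.intercept,
                "Standard error": round(egg.intercept_se, 3) if rounded else egg.intercept_se,
                "P-value": format_pvalue(egg.intercept_pvalue)
                if rounded
                else egg.intercept_pvalue,
                "Q": (round(mr.q_statistic, 2) if rounded else mr.q_statistic)
                if mr
                else float("nan"),
                "Q P-value": (format_pvalue(mr.q_pvalue) if rounded else mr.q_pvalue)
                if mr
                else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=SENSITIVITY_COLUMNS)


def forest_frame(results: Sequence[MrResult]) -> pd.DataFrame:
    """Per-group odds ratio and CI, for external forest-plot rendering."""
    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "n_snps": [r.n_snps for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
        }
    )
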