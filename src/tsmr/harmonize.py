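"""Join exposure instruments to outcome statistics and align effect alleles.

Exposure and outcome studies may report effects for opposite alleles of
the same variant. Harmonization keys the two tables on SNP id and, where
the outcome's effect/other alleles are swapped relative to the exposure,
negates the outcome beta so both effects refer to the same allele.
Palindromic (A/T, C/G) variants — whose strand cannot be resolved from
alleles alone — are flagged and, by default, retained; variants whose
allele pairs cannot be reconciled at all are dropped with a reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from .io import InstrumentTable, SnpAssociation, is_palindromic

logger = logging.getLogger(__name__)

HARMONIZED_COLUMNS = [
    "rsid",
    "cancer_type",
    "smoking_related",
    "effect_allele",
    "other_allele",
    "beta_exposure",
    "se_exposure",
    "pvalue_exposure",
    "beta_outcome",
    "se_outcome",
    "flipped",
    "proxy_used",
    "palindromic",
]


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome pair aligned to a shared effect allele."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    cancer_type: str
    smoking_related: bool = False
    pvalue_exposure: float = float("nan")
    flipped: bool = False
    proxy_used: bool = False
    palindromic: bool = False

    def __post_init__(self) -> None:
        if self.se_exposure <= 0:
            raise ValueError(f"{self.rsid}: se_exposure must be > 0")
        if self.se_outcome <= 0:
            raise ValueError(f"{self.rsid}: se_outcome must be > 0")


@dataclass(frozen=True)
class DroppedInstrument:
    rsid: str
    reason: str  # "absent" | "incompatible"


def harmonize(
    exposure: InstrumentTable,
    outcome: Mapping[str, SnpAssociation],
    drop_palindromic: bool = False,
    proxied_rsids: frozenset[str] | set[str] = frozenset(),
) -> tuple[list[HarmonizedInstrument], list[DroppedInstrument]]:
    """Align each exposure instrument with its outcome record.

    Allele comparison is case-insensitive. Outcomes reported for the
    swapped allele pair have their beta negated (``flipped=True``);
    |beta| and se are never altered. ``proxied_rsids`` marks instruments
    whose outcome record comes through a proxy variant.
    """
    harmonized: list[HarmonizedInstrument] = []
    dropped: list[DroppedInstrument] = []
    for rec in exposure.records:
        out = outcome.get(rec.rsid)
        if out is None:
            dropped.append(DroppedInstrument(rec.rsid, "absent"))
            continue
        exp_pair = (rec.effect_allele, rec.other_allele)
        out_pair = (out.effect_allele, out.other_allele)
        if out_pair == exp_pair:
            beta_y, flipped = out.beta, False
        elif out_pair == exp_pair[::-1]:
            beta_y, flipped = -out.beta, True
        else:
            dropped.append(DroppedInstrument(rec.rsid, "incompatible"))
            continue
        pal = is_palindromic(*exp_pair)
        if pal:
            if drop_palindromic:
                dropped.append(DroppedInstrument(rec.rsid, "palindromic"))
                continue
            logger.warning(
                "%s is palindromic (%s/%s); strand cannot be verified from alleles",
                rec.rsid,
                *exp_pair,
            )
        harmonized.append(
            HarmonizedInstrument(
                rsid=rec.rsid,
                effect_allele=rec.effect_allele,
                other_allele=rec.other_allele,
                beta_exposure=rec.beta,
                se_exposure=rec.se,
                pvalue_exposure=rec.pvalue,
                beta_outcome=beta_y,
                se_outcome=out.se,
                cancer_type=exposure.cancer_type,
                smoking_related=exposure.smoking_related,
                flipped=flipped,
                proxy_used=rec.rsid in set(proxied_rsids),
                palindromic=pal,
            )
        )
    return harmonized, dropped


def harmonized_frame(instruments: list[HarmonizedInstrument]) -> pd.DataFrame:
    """Tabular view of a harmonized set (the pipeline's canonical intermediate)."""
    return pd.DataFrame(
        [{c: getattr(h, c) for c in HARMONIZED_COLUMNS} for h in instruments],
        columns=HARMONIZED_COLUMNS,
    )


def write_harmonized(instruments: list[HarmonizedInstrument], path: str | Path) -> None:
    harmonized_frame(instruments).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_harmonized(path: str | Path) -> list[HarmonizedInstrument]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in HARMONIZED_COLUMNS}
        for flag in ("smoking_related", "flipped", "proxy_used", "palindromic"):
            kwargs[flag] = bool(kwargs[flag])
        out.append(HarmonizedInstrument(**kwargs))
    return out
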