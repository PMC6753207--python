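"""Readers, writers and validation for GWAS summary-statistic tables.

Four tabular inputs feed a two-sample Mendelian randomization analysis:

* exposure *instrument tables* — one row per SNP with its per-allele
  log-odds effect on the exposure trait (here: a cancer type);
* an *outcome table* in the layout used by large case-control
  meta-analyses (one row per marker, keyed by rsID);
* pairwise *LD matrices* of squared allelic correlations (r^2);
* *proxy tables* mapping instruments absent from the outcome data to
  correlated substitutes, with the allele correspondence needed to keep
  effect directions consistent.

All files are plain tab-separated text with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

VALID_ALLELES = frozenset("ACGT")

#: Palindromic allele pairs: strand cannot be resolved from alleles alone.
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

# Default column names for exposure instrument tables (case-insensitive).
EXPOSURE_COLUMNS = {
    "rsid": "rsid",
    "chromosome": "chromosome",
    "position": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "eaf": "eaf",
}

# Default column names for outcome tables, following the IGAP datafile
# layout (Build 37 / Hg19 coordinates).
OUTCOME_COLUMNS = {
    "chromosome": "Chromosome",
    "position": "Position",
    "rsid": "MarkerName",
    "effect_allele": "Effect_allele",
    "other_allele": "Non_Effect_allele",
    "beta": "Beta",
    "se": "SE",
    "pvalue": "P",
}

_FLOAT_FMT = "%.17g"  # lossless for float64 round trips


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G variants (ambiguous strand)."""
    return {a1.upper(), a2.upper()} in _PALINDROMIC_PAIRS


def _clean_allele(value: str, rsid: str, label: str) -> str:
    allele = str(value).strip().upper()
    if allele not in VALID_ALLELES:
        raise ValidationError(
            f"{rsid}: {label} {value!r} is not a single-nucleotide allele (A/C/G/T)"
        )
    return allele


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's association with one trait.

    ``beta`` is the log-odds effect per copy of ``effect_allele``;
    ``se`` its standard error. ``eaf`` (effect-allele frequency) is
    optional — nothing downstream uses it.
    """

    rsid: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None

    def __post_init__(self) -> None:
        if not str(self.rsid).strip():
            raise ValidationError("rsid must be non-empty")
        object.__setattr__(self, "rsid", str(self.rsid).strip())
        object.__setattr__(self, "chromosome", str(self.chromosome))
        object.__setattr__(
            self, "effect_allele", _clean_allele(self.effect_allele, self.rsid, "effect_allele")
        )
        object.__setattr__(
            self, "other_allele", _clean_allele(self.other_allele, self.rsid, "other_allele")
        )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are identical")
        if not np.isfinite(self.beta):
            raise ValidationError(f"{self.rsid}: beta is not finite")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{self.rsid}: se must be finite and > 0, got {self.se}")
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValidationError(f"{self.rsid}: p-value {self.pvalue} outside [0, 1]")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)

    def with_alleles(self, effect_allele: str, other_allele: str) -> "SnpAssociation":
        return replace(self, effect_allele=effect_allele, other_allele=other_allele)


@dataclass(frozen=True)
class InstrumentTable:
    """Ordered set of candidate instruments for one exposure trait."""

    cancer_type: str
    smoking_related: bool
    records: tuple[SnpAssociation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        rsids = [r.rsid for r in self.records]
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise ValidationError(
                f"duplicate rsids in instrument table for {self.cancer_type}: {sorted(dupes)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def subset(self, rsids: Iterable[str]) -> "InstrumentTable":
        keep = set(rsids)
        return replace(self, records=tuple(r for r in self.records if r.rsid in keep))


@dataclass(frozen=True)
class LdMatrix:
    """Symmetric matrix of pairwise squared allelic correlations."""

    rsids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rsids", tuple(self.rsids))
        mat = np.asarray(self.r2, dtype=float)
        n = len(self.rsids)
        if mat.shape != (n, n):
            raise ValidationError(f"LD matrix shape {mat.shape} does not match {n} rsids")
        if not np.allclose(mat, mat.T, atol=1e-9):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(mat), 1.0, atol=1e-9):
            raise ValidationError("LD matrix diagonal must be 1")
        if mat.min() < -1e-12 or mat.max() > 1 + 1e-12:
            raise ValidationError("LD r2 entries must lie in [0, 1]")
        object.__setattr__(self, "r2", np.clip(mat, 0.0, 1.0))
        object.__setattr__(self, "_index", {r: i for i, r in enumerate(self.rsids)})

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def value(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])


@dataclass(frozen=True)
class ProxyCandidate:
    """One (target, proxy) pair with its r^2 and allele correspondence."""

    target_rsid: str
    proxy_rsid: str
    r2: float
    allele_map: Mapping[str, str]  # target allele -> proxy allele

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValidationError(
                f"proxy {self.target_rsid}->{self.proxy_rsid}: r2 {self.r2} outside [0, 1]"
            )
        amap = {str(k).upper(): str(v).upper() for k, v in dict(self.allele_map).items()}
        if len(amap) != 2 or len(set(amap.values())) != 2:
            raise ValidationError(
                f"proxy {self.target_rsid}->{self.proxy_rsid}: allele_map must be a "
                f"bijection over the target's two alleles, got {amap}"
            )
        object.__setattr__(self, "allele_map", amap)


@dataclass(frozen=True)
class ProxyTable:
    """Long-format collection of proxy candidates."""

    rows: tuple[ProxyCandidate, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))

    def __len__(self) -> int:
        return len(self.rows)

    def candidates_for(self, target_rsid: str) -> list[ProxyCandidate]:
        return [r for r in self.rows if r.target_rsid == target_rsid]


# ---------------------------------------------------------------------------
# readers


def _resolve_columns(df: pd.DataFrame, wanted: Mapping[str, str], path, optional=("eaf",)):
    """Map canonical field -> actual dataframe column, case-insensitively."""
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for fieldname, colname in wanted.items():
        actual = lower.get(colname.lower())
        if actual is None:
            if fieldname in optional:
                continue
            raise FormatError(f"{path}: missing required column {colname!r}")
        resolved[fieldname] = actual
    return resolved


def _row_to_association(row: pd.Series, cols: Mapping[str, str], path, line: int) -> SnpAssociation:
    def num(fieldname: str) -> float:
        raw = row[cols[fieldname]]
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}, line {line}: non-numeric {fieldname} value {raw!r}"
            ) from None

    eaf = None
    if "eaf" in cols and not pd.isna(row[cols["eaf"]]):
        eaf = num("eaf")
    try:
        return SnpAssociation(
            rsid=str(row[cols["rsid"]]),
            chromosome=str(row[cols["chromosome"]]) if "chromosome" in cols else "NA",
            position=int(num("position")) if "position" in cols else 0,
            effect_allele=str(row[cols["effect_allele"]]),
            other_allele=str(row[cols["other_allele"]]),
            beta=num("beta"),
            se=num("se"),
            pvalue=num("pvalue"),
            eaf=eaf,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}, line {line}: {exc}") from exc


def read_instrument_table(
    path: str | Path,
    cancer_type: str,
    smoking_related: bool,
    column_map: Mapping[str, str] | None = None,
) -> InstrumentTable:
    """Read an exposure instrument table (TSV with header), preserving row order.

    ``column_map`` overrides the default header names, keyed by canonical
    field name (``rsid``, ``beta``, ``se``, ...).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    wanted = dict(EXPOSURE_COLUMNS)
    if column_map:
        wanted.update(column_map)
    cols = _resolve_columns(df, wanted, path)
    records = [
        _row_to_association(row, cols, path, line=i + 2)  # +2: header + 1-based
        for i, (_, row) in enumerate(df.iterrows())
    ]
    return InstrumentTable(cancer_type=cancer_type, smoking_related=smoking_related, records=records)


def read_outcome_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> dict[str, SnpAssociation]:
    """Read an outcome summary-statistics table, keyed by marker name.

    Marker names are opaque keys: rsIDs or chromosome:position labels are
    both accepted. Duplicate marker names are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    wanted = dict(OUTCOME_COLUMNS)
    if column_map:
        wanted.update(column_map)
    cols = _resolve_columns(df, wanted, path)
    out: dict[str, SnpAssociation] = {}
    for i, (_, row) in enumerate(df.iterrows()):
        rec = _row_to_association(row, cols, path, line=i + 2)
        if rec.rsid in out:
            raise FormatError(f"{path}: duplicate MarkerName {rec.rsid!r}")
        out[rec.rsid] = rec
    return out


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read a square r^2 matrix with rsid row and column labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column rsid labels differ")
    return LdMatrix(rsids=tuple(str(r) for r in df.index), r2=df.to_numpy(dtype=float))


def read_proxy_table(path: str | Path) -> ProxyTable:
    """Read a long-format proxy table.

    Expected columns: target_rsid, proxy_rsid, r2, target_allele,
    proxy_allele — two rows per (target, proxy) pair, one per target allele.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(
        df,
        {c: c for c in ("target_rsid", "proxy_rsid", "r2", "target_allele", "proxy_allele")},
        path,
        optional=(),
    )
    rows = []
    grouped = df.groupby([cols["target_rsid"], cols["proxy_rsid"]], sort=False)
    for (target, proxy), sub in grouped:
        r2_vals = {float(v) for v in sub[cols["r2"]]}
        if len(r2_vals) != 1:
            raise FormatError(f"{path}: inconsistent r2 for pair {target}->{proxy}")
        amap = dict(zip(sub[cols["target_allele"]], sub[cols["proxy_allele"]]))
        rows.append(
            ProxyCandidate(
                target_rsid=str(target),
                proxy_rsid=str(proxy),
                r2=r2_vals.pop(),
                allele_map=amap,
            )
        )
    return ProxyTable(rows=rows)


# ---------------------------------------------------------------------------
# writers


def _association_frame(records: Iterable[SnpAssociation], columns: Mapping[str, str]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            columns["rsid"]: r.rsid,
            columns["chromosome"]: r.chromosome,
            columns["position"]: r.position,
            columns["effect_allele"]: r.effect_allele,
            columns["other_allele"]: r.other_allele,
            columns["beta"]: r.beta,
            columns["se"]: r.se,
            columns["pvalue"]: r.pvalue,
        }
        if "eaf" in columns and r.eaf is not None:
            row[columns["eaf"]] = r.eaf
        rows.append(row)
    return pd.DataFrame(rows)


def write_instrument_table(table: InstrumentTable, path: str | Path) -> None:
    cols = {k: v for k, v in EXPOSURE_COLUMNS.items() if k != "eaf"}
    if any(r.eaf is not None for r in table.records):
        cols["eaf"] = EXPOSURE_COLUMNS["eaf"]
    _association_frame(table.records, cols).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_outcome_table(records: Mapping[str, SnpAssociation] | Iterable[SnpAssociation], path: str | Path) -> None:
    if isinstance(records, Mapping):
        records = records.values()
    _association_frame(records, OUTCOME_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_ld_matrix(ld: LdMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=list(ld.rsids), columns=list(ld.rsids)).to_csv(
        path, sep="\t", float_format=_FLOAT_FMT
    )


def write_proxy_table(proxies: ProxyTable, path: str | Path) -> None:
    rows = []
    for cand in proxies.rows:
        for t_allele, p_allele in cand.allele_map.items():
            rows.append(
                {
                    "target_rsid": cand.target_rsid,
                    "proxy_rsid": cand.proxy_rsid,
                    "r2": cand.r2,
                    "target_allele": t_allele,
                    "proxy_allele": p_allele,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
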