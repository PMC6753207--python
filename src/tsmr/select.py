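"""Instrument selection: significance filter, LD pruning, proxy substitution.

Valid instruments must be genome-wide significant for the exposure,
mutually independent (pairwise r^2 below a pruning threshold, keeping the
lead SNP — the one with the lowest association p-value), and present in
the outcome dataset, either directly or through a high-LD proxy
(r^2 strictly above the proxy threshold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError
from .io import InstrumentTable, LdMatrix, ProxyTable

P_GENOME_WIDE = 5e-8
R2_PRUNE = 0.2
R2_PROXY = 0.9


@dataclass
class SelectionReport:
    """Disposition of every candidate rsid through selection.

    The five groups partition the input rsids: ``kept`` survived all
    stages; ``dropped_significance`` failed the p-value filter;
    ``dropped_ld`` maps each pruned rsid to the retained lead SNP it was
    correlated with; ``proxied`` maps an instrument absent from the
    outcome data to the proxy that replaced it; ``dropped_no_proxy``
    were absent with no qualifying proxy.
    """

    kept: list[str] = field(default_factory=list)
    dropped_significance: list[str] = field(default_factory=list)
    dropped_ld: dict[str, str] = field(default_factory=dict)
    proxied: dict[str, str] = field(default_factory=dict)
    dropped_no_proxy: list[str] = field(default_factory=list)

    def merge(self, other: "SelectionReport") -> "SelectionReport":
        return SelectionReport(
            kept=self.kept + other.kept,
            dropped_significance=self.dropped_significance + other.dropped_significance,
            dropped_ld={**self.dropped_ld, **other.dropped_ld},
            proxied={**self.proxied, **other.proxied},
            dropped_no_proxy=self.dropped_no_proxy + other.dropped_no_proxy,
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "kept": self.kept,
                "dropped_significance": self.dropped_significance,
                "dropped_ld": self.dropped_ld,
                "proxied": self.proxied,
                "dropped_no_proxy": self.dropped_no_proxy,
            },
            **kwargs,
        )

    def all_inputs(self) -> set[str]:
        return (
            set(self.kept)
            | set(self.dropped_significance)
            | set(self.dropped_ld)
            | set(self.proxied)
            | set(self.dropped_no_proxy)
        )


def filter_significant(table: InstrumentTable, threshold: float = P_GENOME_WIDE) -> InstrumentTable:
    """Retain rows with association p-value strictly below ``threshold``.

    The boundary is exclusive: a SNP at exactly p = 5e-8 is dropped.
    Row order is preserved.
    """
    return replace(
        table, records=tuple(r for r in table.records if r.pvalue < threshold)
    )


def ld_prune(
    table: InstrumentTable, ld: LdMatrix, r2_max: float = R2_PRUNE
) -> tuple[InstrumentTable, SelectionReport]:
    """Greedy lead-SNP pruning within one exposure trait.

    SNPs are visited in ascending p-value order (ties broken by rsid);
    each accepted SNP removes every remaining SNP with r^2 >= ``r2_max``
    against it. The result is invariant to input row order, and no
    retained pair violates the threshold.
    """
    missing = [r.rsid for r in table.records if r.rsid not in ld]
    if missing:
        raise ConfigurationError(
            f"rsids absent from the LD matrix for {table.cancer_type}: {missing}"
        )
    ordered = sorted(table.records, key=lambda r: (r.pvalue, r.rsid))
    kept: list = []
    report = SelectionReport()
    for rec in ordered:
        lead = next((k for k in kept if ld.value(rec.rsid, k.rsid) >= r2_max), None)
        if lead is None:
            kept.append(rec)
            report.kept.append(rec.rsid)
        else:
            report.dropped_ld[rec.rsid] = lead.rsid
    return replace(table, records=tuple(kept)), report


def substitute_proxies(
    table: InstrumentTable,
    outcome_rsids: set[str],
    proxies: ProxyTable,
    r2_min: float = R2_PROXY,
) -> tuple[InstrumentTable, SelectionReport]:
    """Replace instruments absent from the outcome data with high-LD proxies.

    An instrument present in ``outcome_rsids`` is returned untouched. An
    absent instrument is replaced by its highest-r^2 proxy with r^2
    strictly above ``r2_min`` whose rsid is in the outcome set; its
    exposure-side beta/se/p are inherited unchanged and its alleles are
    remapped through the proxy's allele correspondence. Absent
    instruments with no qualifying proxy are dropped and listed.
    """
    kept = []
    report = SelectionReport()
    for rec in table.records:
        if rec.rsid in outcome_rsids:
            kept.append(rec)
            report.kept.append(rec.rsid)
            continue
        candidates = [
            c
            for c in proxies.candidates_for(rec.rsid)
            if c.r2 > r2_min and c.proxy_rsid in outcome_rsids
        ]
        if not candidates:
            report.dropped_no_proxy.append(rec.rsid)
            continue
        best = max(candidates, key=lambda c: (c.r2, c.proxy_rsid))
        amap = best.allele_map
        if rec.effect_allele not in amap or rec.other_allele not in amap:
            report.dropped_no_proxy.append(rec.rsid)
            continue
        proxy_rec = replace(
            rec,
            rsid=best.proxy_rsid,
            effect_allele=amap[rec.effect_allele],
            other_allele=amap[rec.other_allele],
        )
        kept.append(proxy_rec)
        report.proxied[rec.rsid] = best.proxy_rsid
    return replace(table, records=tuple(kept)), report


def select_instruments(
    table: InstrumentTable,
    outcome_rsids: set[str] | None = None,
    ld: LdMatrix | None = None,
    proxies: ProxyTable | None = None,
    p_threshold: float = P_GENOME_WIDE,
    r2_prune: float = R2_PRUNE,
    r2_proxy: float = R2_PROXY,
) -> tuple[InstrumentTable, SelectionReport]:
    """Full selection cascade: significance -> LD pruning -> proxy substitution.

    LD pruning runs only when an LD matrix is supplied; proxy substitution
    only when an outcome rsid set is supplied (with an empty proxy table
    by default, so absent instruments are dropped).
    """
    report = SelectionReport()
    sig = filter_significant(table, p_threshold)
    report.dropped_significance = [
        r.rsid for r in table.records if r.rsid not in set(sig.rsids)
    ]
    current = sig
    if ld is not None:
        current, prune_rep = ld_prune(current, ld, r2_prune)
        report.dropped_ld = prune_rep.dropped_ld
    if outcome_rsids is not None:
        current, proxy_rep = substitute_proxies(
            current, outcome_rsids, proxies or ProxyTable(rows=()), r2_proxy
        )
        report.proxied = proxy_rep.proxied
        report.dropped_no_proxy = proxy_rep.dropped_no_proxy
        report.kept = proxy_rep.kept
    else:
        report.kept = list(current.rsids)
    return current, report
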