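"""Significance filtering, greedy LD pruning and proxy substitution."""

import itertools

import numpy as np
import pytest

from tsmr.errors import ConfigurationError
from tsmr.io import InstrumentTable, LdMatrix, ProxyCandidate, ProxyTable
from tsmr.select import (
    filter_significant,
    ld_prune,
    select_instruments,
    substitute_proxies,
)

from conftest import make_snp


def table_of(records, cancer_type="lung", smoking=True):
    return InstrumentTable(cancer_type=cancer_type, smoking_related=smoking,
                           records=records)


class TestSignificanceFilter:
    def test_strictly_below_threshold_kept(self):
        table = table_of([make_snp("rs1", pvalue=4.9e-8)])
        assert filter_significant(table).rsids == ["rs1"]

    def test_boundary_value_dropped(self):
        table = table_of([make_snp("rs1", pvalue=5e-8)])
        assert filter_significant(table).rsids == []

    def test_enumerated_mixed_table(self):
        pvals = [1e-9, 0.2, 3e-8, 5e-8, 0.9, 1e-20, 6e-8, 0.5, 0.04, 1.0]
        table = table_of([make_snp(f"rs{i}", pvalue=p) for i, p in enumerate(pvals)])
        expected_kept = [f"rs{i}" for i, p in enumerate(pvals) if p < 5e-8]
        kept = filter_significant(table)
        assert kept.rsids == expected_kept == ["rs0", "rs2", "rs5"]
        _, report = select_instruments(table)
        assert sorted(report.dropped_significance) == sorted(
            set(table.rsids) - set(expected_kept)
        )


def ld_from(rsids, pairs):
    n = len(rsids)
    idx = {r: i for i, r in enumerate(rsids)}
    r2 = np.zeros((n, n))
    np.fill_diagonal(r2, 1.0)
    for a, b, v in pairs:
        r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = v
    return LdMatrix(tuple(rsids), r2)


class TestLdPrune:
    def test_independent_snps_all_kept(self):
        records = [make_snp(f"rs{i}", pvalue=10 ** -(9 + i)) for i in range(4)]
        ld = ld_from([r.rsid for r in records],
                     [(a.rsid, b.rsid, 0.1) for a, b in itertools.combinations(records, 2)])
        pruned, report = ld_prune(table_of(records), ld)
        assert set(pruned.rsids) == {r.rsid for r in records}
        assert report.dropped_ld == {}

    def test_lead_snp_retained_in_correlated_pair(self):
        records = [make_snp("rsA", pvalue=1e-10), make_snp("rsB", pvalue=1e-9)]
        ld = ld_from(["rsA", "rsB"], [("rsA", "rsB", 0.5)])
        pruned, report = ld_prune(table_of(records), ld)
        assert pruned.rsids == ["rsA"]
        assert report.dropped_ld == {"rsB": "rsA"}

    def test_chain_keeps_ends(self):
        # A-B r2=0.3, B-C r2=0.3, A-C r2=0 with p_A < p_B < p_C: A knocks
        # out B; C is compatible with A.
        records = [make_snp("rsA", pvalue=1e-12), make_snp("rsB", pvalue=1e-11),
                   make_snp("rsC", pvalue=1e-10)]
        ld = ld_from(["rsA", "rsB", "rsC"],
                     [("rsA", "rsB", 0.3), ("rsB", "rsC", 0.3), ("rsA", "rsC", 0.0)])
        pruned, _ = ld_prune(table_of(records), ld)
        assert set(pruned.rsids) == {"rsA", "rsC"}

    def test_missing_rsid_names_the_culprit(self):
        records = [make_snp("rsA"), make_snp("rsMissing")]
        ld = ld_from(["rsA"], [])
        with pytest.raises(ConfigurationError, match="rsMissing"):
            ld_prune(table_of(records), ld)

    def test_order_invariance_and_no_violating_pair(self):
        """Brute-force check on random LD structures: the retained set never
        contains a pair at/above the threshold, selection is p-ordered, and
        shuffling the input rows changes nothing."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(4, 12)
            rsids = [f"rs{i}" for i in range(n)]
            raw = rng.uniform(0, 0.6, (n, n))
            r2 = np.triu(raw, 1)
            r2 = r2 + r2.T
            np.fill_diagonal(r2, 1.0)
            ld = LdMatrix(tuple(rsids), r2)
            records = [make_snp(r, pvalue=float(rng.uniform(1e-30, 1e-8)))
                       for r in rsids]
            pruned, _ = ld_prune(table_of(records), ld)
            for a, b in itertools.combinations(pruned.rsids, 2):
                assert ld.value(a, b) < 0.2
            shuffled = list(records)
            rng.shuffle(shuffled)
            pruned2, _ = ld_prune(table_of(shuffled), ld)
            assert pruned2.rsids == pruned.rsids


class TestProxySubstitution:
    def proxy_table(self):
        return ProxyTable(rows=(
            ProxyCandidate("rsGone", "rsP1", 0.92, {"A": "T", "G": "C"}),
            ProxyCandidate("rsGone", "rsP2", 0.97, {"A": "C", "G": "T"}),
            ProxyCandidate("rsEdge", "rsP3", 0.9, {"A": "T", "G": "C"}),
        ))

    def test_present_instrument_untouched(self):
        table = table_of([make_snp("rsHere", beta=0.12, pvalue=1e-9)])
        out, report = substitute_proxies(table, {"rsHere"}, self.proxy_table())
        assert out.records == table.records
        assert report.kept == ["rsHere"]

    def test_boundary_r2_not_used(self):
        table = table_of([make_snp("rsEdge")])
        out, report = substitute_proxies(table, {"rsP3"}, self.proxy_table())
        assert len(out) == 0
        assert report.dropped_no_proxy == ["rsEdge"]

    def test_best_proxy_chosen_and_alleles_remapped(self):
        table = table_of([make_snp("rsGone", beta=0.2, se=0.02, pvalue=1e-15,
                                   ea="A", oa="G")])
        out, report = substitute_proxies(table, {"rsP1", "rsP2"}, self.proxy_table())
        assert report.proxied == {"rsGone": "rsP2"}
        rec = out.records[0]
        # 0.97 candidate maps A->C, G->T; exposure stats inherited unchanged
        assert (rec.rsid, rec.effect_allele, rec.other_allele) == ("rsP2", "C", "T")
        assert (rec.beta, rec.se, rec.pvalue) == (0.2, 0.02, 1e-15)

    def test_proxy_must_be_in_outcome_set(self):
        table = table_of([make_snp("rsGone")])
        out, report = substitute_proxies(table, {"rsP1"}, self.proxy_table())
        assert report.proxied == {"rsGone": "rsP1"}
        assert out.records[0].rsid == "rsP1"

    def test_non_proxied_betas_never_changed(self):
        rng = np.random.default_rng(5)
        records = [make_snp(f"rs{i}", beta=float(rng.normal()), pvalue=1e-9)
                   for i in range(6)]
        table = table_of(records)
        out, _ = substitute_proxies(table, {r.rsid for r in records},
                                    ProxyTable(rows=()))
        assert out.records == table.records


class TestSelectionReportPartition:
    def test_groups_partition_the_input(self):
        records = [
            make_snp("rsKeep", pvalue=1e-10),
            make_snp("rsWeak", pvalue=0.5),
            make_snp("rsTag", pvalue=1e-9),
            make_snp("rsGone", pvalue=1e-12),
            make_snp("rsLost", pvalue=1e-12),
        ]
        ld = ld_from([r.rsid for r in records],
                     [("rsKeep", "rsTag", 0.8)])
        proxies = ProxyTable(rows=(
            ProxyCandidate("rsGone", "rsP", 0.95, {"A": "T", "G": "C"}),
        ))
        outcome = {"rsKeep", "rsP"}
        table = table_of(records)
        _, report = select_instruments(table, outcome, ld=ld, proxies=proxies)
        groups = [set(report.kept), set(report.dropped_significance),
                  set(report.dropped_ld), set(report.proxied),
                  set(report.dropped_no_proxy)]
        assert report.all_inputs() == set(table.rsids)
        for a, b in itertools.combinations(groups, 2):
            assert not (a & b)
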