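"""Wald ratios and fixed-effect inverse-variance weighted pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmr.errors import ConfigurationError, InsufficientInstrumentsError
from tsmr.mr import RatioEstimate, ivw_pool, pool_groups, wald_ratio

from conftest import make_harmonized, random_harmonized


class TestWaldRatio:
    def test_direct_substitution(self):
        h = make_harmonized("rs1", beta_x=0.1, beta_y=-0.02, se_y=0.01)
        r = wald_ratio(h)
        assert r.theta == pytest.approx(-0.2)
        assert r.variance == pytest.approx(0.01)
        assert r.weight == pytest.approx(100.0)

    def test_zero_outcome_effect(self):
        h = make_harmonized("rs1", beta_x=0.3, beta_y=0.0, se_y=0.01)
        assert wald_ratio(h).theta == 0.0

    def test_zero_exposure_effect_is_an_error(self):
        h = make_harmonized("rs1", beta_x=0.0, beta_y=0.1, se_y=0.01)
        with pytest.raises(ZeroDivisionError, match="rs1"):
            wald_ratio(h)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        beta_x=st.floats(0.01, 2.0).flatmap(lambda b: st.sampled_from([b, -b])),
        beta_y=st.floats(-1.0, 1.0),
        se_y=st.floats(1e-4, 0.5),
    )
    def test_variance_matches_algebraic_rearrangement(self, beta_x, beta_y, se_y):
        h = make_harmonized("rs1", beta_x=beta_x, beta_y=beta_y, se_y=se_y)
        assert wald_ratio(h).variance == pytest.approx((se_y / beta_x) ** 2, rel=1e-12)


class TestIvwPool:
    def test_equal_weight_symmetry(self):
        ratios = [RatioEstimate("rs1", -0.1, 0.04), RatioEstimate("rs2", -0.3, 0.04)]
        assert ivw_pool(ratios).theta_ivw == pytest.approx(-0.2)

    def test_requires_two_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw_pool([RatioEstimate("rs1", -0.1, 0.04)], group="cervical")

    def test_matches_no_intercept_wls_slope(self):
        """The printed estimator form equals the zero-intercept weighted
        least-squares slope of beta_Y on beta_X with weights se_Y^-2."""
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        for _ in range(10):
            harmonized = random_harmonized(rng, int(rng.integers(5, 40)), theta=-0.1)
            res = ivw_pool([wald_ratio(h) for h in harmonized])
            bx = np.array([h.beta_exposure for h in harmonized])
            by = np.array([h.beta_outcome for h in harmonized])
            w = np.array([h.se_outcome for h in harmonized]) ** -2.0
            slope = sm.WLS(by, bx[:, None], weights=w).fit().params[0]
            assert res.theta_ivw == pytest.approx(slope, abs=1e-12)

    def test_weighted_mean_equals_printed_form(self):
        """Sum w_j theta_j / sum w_j is algebraically the ratio of the two
        weighted cross-products in the printed formula."""
        rng = np.random.default_rng(8)
        harmonized = random_harmonized(rng, 25, theta=0.2)
        res = ivw_pool([wald_ratio(h) for h in harmonized])
        bx = np.array([h.beta_exposure for h in harmonized])
        by = np.array([h.beta_outcome for h in harmonized])
        inv_v = np.array([h.se_outcome for h in harmonized]) ** -2.0
        printed = np.sum(by * bx * inv_v) / np.sum(bx**2 * inv_v)
        assert res.theta_ivw == pytest.approx(printed, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        ratios = [RatioEstimate(f"rs{i}", float(rng.normal()), float(rng.uniform(0.01, 1)))
                  for i in range(15)]
        shuffled = list(ratios)
        rng.shuffle(shuffled)
        a, b = ivw_pool(ratios), ivw_pool(shuffled)
        assert a.theta_ivw == pytest.approx(b.theta_ivw, rel=1e-14)
        assert a.se_ivw == pytest.approx(b.se_ivw, rel=1e-14)

    def test_scale_consistency(self):
        """Multiplying every beta_X by c and every (beta_Y, se_Y) by c
        leaves the pooled estimate unchanged."""
        rng = np.random.default_rng(4)
        harmonized = random_harmonized(rng, 20, theta=-0.05)
        c = 3.7
        scaled = [make_harmonized(h.rsid, c * h.beta_exposure, c * h.beta_outcome,
                                  c * h.se_outcome) for h in harmonized]
        a = ivw_pool([wald_ratio(h) for h in harmonized])
        b = ivw_pool([wald_ratio(h) for h in scaled])
        assert a.theta_ivw == pytest.approx(b.theta_ivw, rel=1e-12)

    def test_dominant_weight_limit(self):
        ratios = [RatioEstimate("rsBig", 0.42, 1e-10),
                  RatioEstimate("rsSmall", -3.0, 10.0)]
        assert ivw_pool(ratios).theta_ivw == pytest.approx(0.42, abs=1e-6)

    def test_ci_brackets_odds_ratio(self):
        rng = np.random.default_rng(6)
        res = ivw_pool([wald_ratio(h) for h in random_harmonized(rng, 12)])
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_pvalue_is_two_sided_normal_tail(self):
        from scipy import stats

        ratios = [RatioEstimate("rs1", -0.1, 0.04), RatioEstimate("rs2", -0.3, 0.04)]
        res = ivw_pool(ratios)
        z = res.theta_ivw / res.se_ivw
        assert res.pvalue == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-12)


class TestGroupPooling:
    def two_cancer_set(self):
        rng = np.random.default_rng(9)
        lung = random_harmonized(rng, 6, theta=-0.05, cancer_type="lung")
        lung = [make_harmonized(h.rsid, h.beta_exposure, h.beta_outcome,
                                h.se_outcome, cancer_type="lung",
                                smoking_related=True) for h in lung]
        breast = random_harmonized(rng, 8, theta=-0.05, cancer_type="breast")
        return lung + breast

    def test_per_cancer_grouping(self):
        results = pool_groups(self.two_cancer_set(), "per-cancer")
        assert {r.group: r.n_snps for r in results} == {"lung": 6, "breast": 8}

    def test_all_grouping_conserves_count(self):
        results = pool_groups(self.two_cancer_set(), "all")
        assert len(results) == 1 and results[0].n_snps == 14

    def test_smoking_split(self):
        instruments = self.two_cancer_set()
        smoking = pool_groups(instruments, "smoking")
        non_smoking = pool_groups(instruments, "non-smoking")
        assert smoking[0].n_snps == 6 and non_smoking[0].n_snps == 8

    def test_pooled_se_smaller_than_either_group(self):
        """Sharing a true effect, the pooled analysis gains precision."""
        instruments = self.two_cancer_set()
        per = pool_groups(instruments, "per-cancer")
        pooled = pool_groups(instruments, "all")[0]
        assert all(pooled.se_ivw < r.se_ivw for r in per)

    def test_cross_cancer_duplicates_retained_unless_deduped(self):
        rng = np.random.default_rng(10)
        a = random_harmonized(rng, 5, cancer_type="lung")
        b = [make_harmonized(h.rsid, h.beta_exposure, h.beta_outcome, h.se_outcome,
                             cancer_type="breast") for h in a]  # same rsids
        both = a + b
        assert pool_groups(both, "all")[0].n_snps == 10
        assert pool_groups(both, "all", dedupe=True)[0].n_snps == 5

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ConfigurationError):
            pool_groups(self.two_cancer_set(), "by-chromosome")

    def test_single_instrument_groups_skipped(self):
        rng = np.random.default_rng(11)
        one = random_harmonized(rng, 1, cancer_type="cervical")
        results = pool_groups(one + self.two_cancer_set(), "per-cancer")
        assert "cervical" not in {r.group for r in results}
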