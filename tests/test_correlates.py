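"""Composite scores and the statistical engines behind the correlates."""

import numpy as np
import pandas as pd
import pytest

from cogprof.correlates import (
    ClinicalCorrelates,
    binned_group_test,
    cohort_composites,
    compare_groups_ancova,
    composite_t,
    correlate_composites,
    correlate_covariate,
)
from cogprof.domains import default_domain_map
from cogprof.exceptions import DegenerateTableError, UndefinedCorrelationError


def t_table(patient_id, values_by_score):
    rows = [(patient_id, s, s, v) for s, v in values_by_score.items()]
    return pd.DataFrame(rows, columns=["patient_id", "test_id", "score_id", "t_score"])


@pytest.fixture(scope="module")
def dmap():
    return default_domain_map()


class TestCompositeT:
    def test_hand_mean_over_lltm(self, dmap):
        scores = dict(zip(dmap.scores_in("L+LTM"), [38, 42, 45, 55, 50, 40]))
        assert composite_t(t_table("p", scores), dmap, "L+LTM") == pytest.approx(45.0)

    def test_symmetry_and_constant(self, dmap):
        two = dict(zip(dmap.scores_in("ST/WM"), [40.0, 60.0]))
        assert composite_t(t_table("p", two), dmap, "ST/WM") == pytest.approx(50.0)
        flat = {s: 50.0 for s in dmap.scores_in("EF")}
        assert composite_t(t_table("p", flat), dmap, "EF") == pytest.approx(50.0)

    def test_order_and_duplication_invariance(self, dmap):
        scores = dict(zip(dmap.scores_in("Language"), [41.0, 52.0, 63.0]))
        a = composite_t(t_table("p", scores), dmap, "Language")
        rev = dict(reversed(list(scores.items())))
        assert composite_t(t_table("p", rev), dmap, "Language") == pytest.approx(a)

    def test_low_coverage_is_flagged_nan(self, dmap):
        one = {"CPT-II - Omissions": 30.0}  # 1 of 12 Attention scores
        assert np.isnan(composite_t(t_table("p", one), dmap, "Attention"))


class TestPearson:
    def test_matches_hand_covariance_ratio(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.0, 1.0, 5.0, 8.0, 9.0])
        comp = pd.DataFrame({"A": x, "B": y})
        r, p = correlate_composites(comp, ("A", "B"))
        xm, ym = x - x.mean(), y - y.mean()
        r_hand = float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
        assert r == pytest.approx(r_hand, abs=1e-12)
        # two-tailed p from the t distribution with n-2 df
        from scipy.stats import t as t_dist

        t_stat = r_hand * np.sqrt(3 / (1 - r_hand**2))
        assert p == pytest.approx(2 * t_dist.sf(abs(t_stat), 3), abs=1e-12)

    def test_perfect_correlation(self):
        comp = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [2.0, 4.0, 6.0]})
        r, _ = correlate_composites(comp, ("A", "B"))
        assert r == pytest.approx(1.0)

    def test_pairwise_deletion(self):
        comp = pd.DataFrame({"A": [1.0, 2.0, 3.0, np.nan, 5.0],
                             "B": [1.1, 2.2, 2.9, 4.0, np.nan]})
        r, _ = correlate_composites(comp, ("A", "B"))  # 3 complete pairs
        assert -1.0 <= r <= 1.0

    @pytest.mark.parametrize(
        "a, b",
        [([1.0, 2.0], [1.0, 2.0]),            # too few pairs
         ([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])],  # zero variance
    )
    def test_undefined_cases(self, a, b):
        comp = pd.DataFrame({"A": a, "B": b})
        with pytest.raises(UndefinedCorrelationError):
            correlate_composites(comp, ("A", "B"))

    def test_sampling_distribution_recovers_planted_rho(self):
        """Mean sample r over bivariate-normal replicates at n = 63 recovers
        the planted rho = 0.31 within 0.02."""
        rng = np.random.default_rng(99)
        rho, reps = 0.31, 400
        rs = []
        for _ in range(reps):
            x = rng.standard_normal(63)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(63)
            rs.append(correlate_composites(pd.DataFrame({"A": x, "B": y}),
                                           ("A", "B"))[0])
        assert np.mean(rs) == pytest.approx(rho, abs=0.02)


def ancova_f_oracle(y, g, c):
    """Extra-sum-of-squares F for the group term, via lstsq from scratch."""
    X_full = np.column_stack([np.ones_like(y), g, c])
    X_red = np.column_stack([np.ones_like(y), c])
    rss = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
    n = len(y)
    return ((rss(X_red) - rss(X_full)) / 1.0) / (rss(X_full) / (n - 3))


class TestAncova:
    def test_matches_extra_sum_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        g = np.repeat([0.0, 1.0], 30)
        c = rng.normal(50, 12, 60)
        y = 20 - 0.1 * c + 2.0 * g + rng.standard_normal(60)
        F, df, p = compare_groups_ancova(y, g, c)
        assert F == pytest.approx(ancova_f_oracle(y, g, c), rel=1e-10)
        assert df == (1, 57)
        assert 0.0 <= p <= 1.0

    def test_identical_groups_give_f_near_zero(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(40)
        y = np.concatenate([base, base])
        g = np.repeat([0.0, 1.0], 40)
        c = np.concatenate([np.arange(40.0), np.arange(40.0)])
        F, _, p = compare_groups_ancova(y, g, c)
        assert F == pytest.approx(0.0, abs=1e-20)

    def test_reduces_to_one_way_anova_without_covariate_effect(self):
        """When the covariate column carries no unique information beyond
        noise orthogonal to everything, the group F approaches the plain
        ANOVA F computed from scratch."""
        from scipy.stats import f_oneway

        rng = np.random.default_rng(3)
        g = np.repeat([0.0, 1.0], 50)
        y = rng.standard_normal(100) + 0.8 * g
        # covariate orthogonalized against [1, g, y]
        c = rng.standard_normal(100)
        Q = np.column_stack([np.ones(100), g, y])
        c = c - Q @ np.linalg.lstsq(Q, c, rcond=None)[0]
        F, _, _ = compare_groups_ancova(y, g, c)
        F_anova = f_oneway(y[g == 0], y[g == 1]).statistic
        assert F == pytest.approx(F_anova * (97 / 98), rel=1e-10)  # df-only change

    def test_singular_design_rejected(self):
        y = np.arange(10.0)
        g = np.repeat([0.0, 1.0], 5)
        with pytest.raises(np.linalg.LinAlgError):
            compare_groups_ancova(y, g, g)  # covariate == group


class TestBinnedGroupTest:
    def make(self, imp_a, avg_a, imp_b, avg_b):
        rows, pid = [], 0
        group = {}
        for n, band, hosp in ((imp_a, "impaired", True), (avg_a, "average_plus", True),
                              (imp_b, "impaired", False), (avg_b, "average_plus", False)):
            for _ in range(n):
                rows.append((f"p{pid}", "WAIS-IV - Coding test", "Coding", band))
                group[f"p{pid}"] = hosp
                pid += 1
        scored = pd.DataFrame(rows, columns=["patient_id", "score_id", "test_id", "band3"])
        return scored, pd.Series(group)

    def test_hand_computed_2x2(self):
        scored, group = self.make(10, 20, 20, 10)
        chi2, dof, p, table = binned_group_test(scored, "WAIS-IV - Coding test",
                                                group, bins="combined")
        assert chi2 == pytest.approx(20.0 / 3.0, abs=1e-12)  # sum (O-E)^2/E by hand
        assert dof == 1

    def test_identical_distributions_give_zero(self):
        scored, group = self.make(15, 15, 15, 15)
        chi2, _, p, _ = binned_group_test(scored, "WAIS-IV - Coding test", group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_degenerate_table_rejected(self):
        scored, group = self.make(10, 0, 12, 0)  # nobody above the cut
        with pytest.raises(DegenerateTableError):
            binned_group_test(scored, "WAIS-IV - Coding test", group)

    def test_planted_difference_detected_with_expected_power(self):
        """With impaired fractions 0.4 vs 0.1 at n = 30/30 the Monte-Carlo
        rejection rate at alpha = .05 matches the exactly enumerated power
        of the uncorrected chi-square (~0.80) within sampling error."""
        import warnings

        from scipy.stats import binom, chi2_contingency

        # exact power by enumerating both binomial counts
        exact = 0.0
        for a in range(31):
            for b in range(31):
                tab = np.array([[a, 30 - a], [b, 30 - b]])
                if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
                    continue
                if chi2_contingency(tab, correction=False)[1] < 0.05:
                    exact += float(binom.pmf(a, 30, 0.4) * binom.pmf(b, 30, 0.1))
        assert 0.70 <= exact <= 0.90  # a well-powered design, per construction

        rng = np.random.default_rng(12)
        hits, reps = 0, 500
        for _ in range(reps):
            a_imp = int(rng.binomial(30, 0.4))
            b_imp = int(rng.binomial(30, 0.1))
            scored, group = self.make(a_imp, 30 - a_imp, b_imp, 30 - b_imp)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, _, p, _ = binned_group_test(scored, "WAIS-IV - Coding test",
                                                   group)
            except DegenerateTableError:
                continue
            hits += p < 0.05
        assert hits / reps == pytest.approx(exact, abs=0.06)


class TestCovariateCorrelations:
    def test_constant_covariate_flagged_per_domain(self):
        comp = pd.DataFrame({"Attention": [40.0, 50.0, 60.0, 45.0]},
                            index=pd.Index(list("abcd"), name="patient_id"))
        cov = pd.DataFrame({"patient_id": list("abcd"), "CRP": [5.0] * 4})
        out = correlate_covariate(comp, cov, "CRP")
        assert out.loc[0, "note"] != ""
        assert np.isnan(out.loc[0, "r"])

    def test_near_identity_covariate(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(50, 10, 40)
        comp = pd.DataFrame({"EF": vals},
                            index=pd.Index(range(40), name="patient_id"))
        cov = pd.DataFrame({"patient_id": range(40),
                            "CK": vals + rng.normal(0, 0.5, 40)})
        out = correlate_covariate(comp, cov, "CK", holm=True)
        assert out.loc[0, "r"] > 0.99
        assert out.loc[0, "p_holm"] >= out.loc[0, "p"]


class TestResultsObject:
    def test_fit_produces_pairwise_table(self, calibrated_scored):
        covs = pd.DataFrame(
            {
                "patient_id": sorted(calibrated_scored.patient_id.unique()),
            }
        )
        rng = np.random.default_rng(5)
        covs["age"] = rng.normal(51, 12, len(covs)).round(1)
        covs["hospitalized"] = rng.random(len(covs)) < 0.52
        covs["MoCA"] = rng.normal(17, 3, len(covs)).round()
        res = ClinicalCorrelates(calibrated_scored, covs).fit()
        assert len(res.domain_correlations) == 21  # 7 choose 2
        assert res.domain_correlations.p.dropna().between(0, 1).all()
        F, df, p = res.compare_groups("MoCA")
        assert df[0] == 1 and 0 <= p <= 1
        binned = res.binned_tests()
        assert len(binned) == 33
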