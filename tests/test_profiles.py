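"""Distribution tables and the 50% / 30%+30% affected-domain rule."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from cogprof.battery import PUBLISHED_BAND_COUNTS, PUBLISHED_BAND_PERCENTAGES
from cogprof.exceptions import UnevaluableDomainError, UnmappedScoreError
from cogprof.profiles import (
    ClassificationThresholds,
    ImpairmentAnalysis,
    ImpairmentProfile,
    banded_cohort_from_counts,
    check_against_published,
    classify_domain,
    cohort_profile_summary,
    impairment_profile,
    score_distribution_table,
)
from conftest import make_scored


def brute_force_affected(n_imp: int, n_low: int, n_avg: int) -> bool:
    """Independent restatement of the rule from raw counts."""
    n = n_imp + n_low + n_avg
    return (n_imp * 2 >= n) or (n_imp * 10 >= 3 * n and n_low * 10 >= 3 * n)


class TestDistributionTable:
    def test_published_counts_reproduce_published_percentages(self):
        """Replaying the published per-score counts reproduces every printed
        percentage to 2 decimals, except the internally inconsistent
        RAVLT - Recognition row, which is flagged."""
        table = score_distribution_table(
            banded_cohort_from_counts(PUBLISHED_BAND_COUNTS)
        )
        check = check_against_published(table, PUBLISHED_BAND_PERCENTAGES)
        flagged = check.loc[~check.consistent, "score_id"].tolist()
        assert flagged == ["RAVLT - Recognition"]

    @pytest.mark.parametrize(
        "score, expected",
        [
            ("RAVLT - Total", (25.40, 26.98, 47.62, 52.38)),
            ("CPT-II - Hit SE", (52.38, 25.40, 22.22, 77.78)),
            ("Stroop - Color", (32.79, 16.39, 50.82, 49.18)),
        ],
    )
    def test_reference_rows(self, score, expected):
        table = score_distribution_table(
            banded_cohort_from_counts({score: PUBLISHED_BAND_COUNTS[score]})
        )
        row = table.iloc[0]
        got = (row.pct_impaired, row.pct_low_avg, row.pct_avg_plus, row.pct_below_24)
        assert got == pytest.approx(expected, abs=5e-3)

    def test_reduced_denominator(self):
        table = score_distribution_table(
            banded_cohort_from_counts({"Stroop - Color": (20, 10, 31)})
        )
        assert table.iloc[0].n_total == 61
        assert table.iloc[0].pct_impaired == pytest.approx(32.79)

    def test_all_average_plus(self):
        table = score_distribution_table(
            banded_cohort_from_counts({"TMT-A": (0, 0, 40)})
        )
        row = table.iloc[0]
        assert (row.pct_impaired, row.pct_low_avg, row.pct_avg_plus) == (0.0, 0.0, 100.0)

    def test_unmapped_score_named_in_error(self):
        with pytest.raises(UnmappedScoreError, match="Mystery"):
            score_distribution_table(banded_cohort_from_counts({"Mystery": (1, 1, 1)}))


class TestClassifyDomain:
    @pytest.mark.parametrize(
        "bands, expected",
        [
            (["impaired"] * 3 + ["average_plus"] * 3, True),     # 50% rule
            (["impaired"] * 2 + ["low_average"] * 2 + ["average_plus"] * 2, True),
            (["impaired", "low_average"] + ["average_plus"] * 4, False),
            (["impaired"], True),                                 # single score
            (["low_average"] * 6, False),                         # low only
        ],
    )
    def test_reference_cases(self, bands, expected):
        assert classify_domain(bands) is expected

    def test_empty_domain_is_unevaluable(self):
        with pytest.raises(UnevaluableDomainError):
            classify_domain([])
        with pytest.raises(UnevaluableDomainError):
            classify_domain([np.nan, None])

    def test_agrees_with_brute_force_over_all_compositions(self):
        """Exhaustive agreement with an independent restatement of the rule
        for every band composition of domain sizes 1-12."""
        for n in range(1, 13):
            for n_imp in range(n + 1):
                for n_low in range(n - n_imp + 1):
                    n_avg = n - n_imp - n_low
                    labels = (["impaired"] * n_imp + ["low_average"] * n_low
                              + ["average_plus"] * n_avg)
                    assert classify_domain(labels) == brute_force_affected(
                        n_imp, n_low, n_avg
                    ), (n_imp, n_low, n_avg)

    def test_order_invariance_on_sequences(self):
        for seq in product(("impaired", "low_average", "average_plus"), repeat=5):
            assert classify_domain(list(seq)) == classify_domain(sorted(seq))

    def test_monotone_in_band_severity(self):
        """Worsening any single score's band never flips affected -> not."""
        worse = {"average_plus": "low_average", "low_average": "impaired"}
        for n in range(1, 9):
            for seq in product(("impaired", "low_average", "average_plus"), repeat=n):
                if not classify_domain(list(seq)):
                    continue
                for i, b in enumerate(seq):
                    if b in worse:
                        mutated = list(seq)
                        mutated[i] = worse[b]
                        assert classify_domain(mutated), (seq, i)

    def test_custom_thresholds(self):
        strict = ClassificationThresholds(impaired_only=1.0,
                                          impaired_combined=1.0,
                                          low_average_combined=1.0)
        assert classify_domain(["impaired", "average_plus"], strict) is False
        assert classify_domain(["impaired", "impaired"], strict) is True


class TestImpairmentProfile:
    def test_clean_patient(self, default_map):
        rows = [("p1", s, "average_plus") for s in default_map]
        prof = impairment_profile(make_scored(rows), default_map)
        assert prof.affected == frozenset()
        assert prof.profile_class == "none"

    def test_single_domain_attention(self, default_map):
        rows = []
        for s in default_map:
            if default_map.domain_of(s) == "Attention":
                band = "impaired" if len(rows) % 2 == 0 else "average_plus"
            else:
                band = "average_plus"
            rows.append(("p1", s, band))
        prof = impairment_profile(make_scored(rows), default_map)
        assert prof.affected == frozenset({"Attention"})
        assert prof.profile_class == "single"

    def test_multi_domain(self, default_map):
        hit = {"Attention", "EF", "L+LTM"}
        rows = [
            ("p1", s, "impaired" if default_map.domain_of(s) in hit else "average_plus")
            for s in default_map
        ]
        prof = impairment_profile(make_scored(rows), default_map)
        assert prof.affected == hit
        assert prof.n_affected == 3
        assert prof.profile_class == "multi"

    def test_low_coverage_domain_is_unevaluable_not_clean(self, default_map):
        rows = [("p1", s, "average_plus") for s in default_map
                if default_map.domain_of(s) != "Attention"]
        rows.append(("p1", "CPT-II - Omissions", "impaired"))  # 1 of 12 observed
        prof = impairment_profile(make_scored(rows), default_map)
        assert "Attention" in prof.unevaluable
        assert "Attention" not in prof.affected

    def test_no_evaluable_domain_raises(self, default_map):
        rows = [("p1", "CPT-II - Omissions", "impaired")]
        with pytest.raises(UnevaluableDomainError):
            impairment_profile(make_scored(rows), default_map)


class TestCohortSummary:
    def test_single_multi_frequencies_and_chi_square(self):
        profiles = (
            [ImpairmentProfile(i, frozenset({"Attention", "EF"})) for i in range(38)]
            + [ImpairmentProfile(100 + i, frozenset({"Attention"})) for i in range(25)]
        )
        s = cohort_profile_summary(profiles)
        assert s.class_freq["multi"] * 100 == pytest.approx(60.32, abs=5e-3)
        assert s.class_freq["single"] * 100 == pytest.approx(39.68, abs=5e-3)
        # 1-df equal-expectation goodness of fit, no continuity correction
        assert s.chi2_single_vs_multi == pytest.approx((38 - 31.5) ** 2 / 31.5 * 2)
        assert 0.0 <= s.chi2_p <= 1.0

    def test_all_single_degenerate_chi_square(self):
        profiles = [ImpairmentProfile(i, frozenset({"EF"})) for i in range(10)]
        s = cohort_profile_summary(profiles)
        assert s.chi2_single_vs_multi == pytest.approx(10.0)
        assert s.class_counts["multi"] == 0

    def test_cooccurrence_symmetric_with_diagonal_counts(self):
        profiles = [
            ImpairmentProfile(1, frozenset({"Attention", "EF"})),
            ImpairmentProfile(2, frozenset({"Attention"})),
        ]
        s = cohort_profile_summary(profiles, domains=("Attention", "EF"))
        co = s.cooccurrence
        assert co.loc["Attention", "Attention"] == 2
        assert co.loc["Attention", "EF"] == co.loc["EF", "Attention"] == 1

    def test_end_to_end_results_object(self, calibrated_scored, default_map):
        res = ImpairmentAnalysis(calibrated_scored, default_map).fit()
        assert len(res.profiles) == 500
        assert set(res.profiles.profile_class) <= {"none", "single", "multi"}
        assert len(res.distribution) == 33
        assert "Cohort impairment summary" in res.summary()
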