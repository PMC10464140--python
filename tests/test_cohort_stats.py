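"""Cohort tallies, the exact binomial enrichment test, expression filtering,
and goodness-of-fit."""

import itertools
import math
import time

import numpy as np
import pytest

from paraloci.cohort_stats import (
    PatientRecord,
    binomial_enrichment,
    filter_expression,
    gof_test,
    load_cohort_fixture,
    tally_alleles,
)


@pytest.fixture(scope="module")
def cohort_tally():
    return tally_alleles(load_cohort_fixture())


class TestTally:
    def test_most_common_allele_count(self, cohort_tally):
        assert cohort_tally.counts["E"] == 18

    def test_shared_region_alleles_count(self, cohort_tally):
        assert cohort_tally.counts["C"] + cohort_tally.counts["E"] == 24

    def test_haplotype_informative_partition(self, cohort_tally):
        assert cohort_tally.n_haplotype_informative == 51
        assert cohort_tally.n_variant_background == 45
        assert cohort_tally.variant_fraction == pytest.approx(0.882, abs=5e-4)

    def test_distinct_allele_classes(self, cohort_tally):
        assert cohort_tally.n_distinct == 8

    def test_patients_with_resolved_alleles(self, cohort_tally):
        assert cohort_tally.n_patients == 33
        assert cohort_tally.n_patients_resolved == 28

    def test_empty_records_give_zero_tally(self):
        t = tally_alleles([])
        assert t.n_total == 0 and t.n_distinct == 0

    def test_unknown_label_listed_in_error(self):
        bad = [PatientRecord("p", "f", ["Z"], "HET")]
        with pytest.raises(ValueError, match=r"\['Z'\]"):
            tally_alleles(bad)

    def test_reordering_never_changes_the_tally(self):
        records = load_cohort_fixture()
        t1 = tally_alleles(records)
        t2 = tally_alleles(list(reversed(records)))
        assert t1.counts == t2.counts

    def test_zygosity_multiplicity(self):
        records = [
            PatientRecord("p1", "f1", ["B"], "HOM"),
            PatientRecord("p2", "f2", ["B", "F"], "COMPOUND_HET"),
            PatientRecord("p3", "f3", ["F"], "HET"),
        ]
        t = tally_alleles(records)
        assert t.counts["B"] == 3 and t.counts["F"] == 2


class TestBinomialEnrichment:
    def test_cohort_value_to_three_significant_figures(self):
        t0 = time.perf_counter()
        res = binomial_enrichment(45, 51, 0.5)
        assert time.perf_counter() - t0 < 1.0
        assert res.p_value == pytest.approx(9.16e-9, rel=5e-3)

    def test_full_upper_tail_is_one(self):
        assert binomial_enrichment(0, 17, 0.5).p_value == 1.0

    def test_single_term_tail(self):
        assert binomial_enrichment(12, 12, 0.5).p_value == pytest.approx(0.5**12)

    @pytest.mark.parametrize("n", [6, 11])
    def test_exactness_against_brute_force_enumeration(self, n):
        # enumerate all 2^n equiprobable outcomes at p0 = 0.5
        for k in range(n + 1):
            brute = sum(
                1 for bits in itertools.product((0, 1), repeat=n)
                if sum(bits) >= k
            ) / 2**n
            assert binomial_enrichment(k, n, 0.5).p_value == pytest.approx(
                brute, rel=1e-12
            )

    def test_two_sided_option(self):
        res = binomial_enrichment(9, 10, 0.5, side="two-sided")
        from scipy.stats import binomtest

        ref = binomtest(9, 10, 0.5, alternative="two-sided").pvalue
        assert res.p_value == pytest.approx(ref, rel=1e-9)

    @pytest.mark.parametrize("k,n,p0", [(-1, 5, 0.5), (6, 5, 0.5), (1, 5, 0.0)])
    def test_invalid_inputs(self, k, n, p0):
        with pytest.raises(ValueError):
            binomial_enrichment(k, n, p0)


class TestFilterExpression:
    def test_all_retained_below_threshold(self):
        x, rep = filter_expression([1, 2, 3], threshold=50, outlier_rule=None)
        assert list(x) == [1, 2, 3] and rep.retained_fraction == 1.0

    def test_threshold_removes_large_values(self):
        x, rep = filter_expression([1, 2, 1000], threshold=50, outlier_rule=None)
        assert list(x) == [1, 2]
        assert rep.retained_fraction == pytest.approx(2 / 3)

    def test_direction_configurable(self):
        x, _ = filter_expression([1, 2, 1000], threshold=50, outlier_rule=None,
                                 direction="gt")
        assert list(x) == [1000]

    def test_matches_naive_scan_on_contaminated_gamma_sample(self):
        # oracle: direct application of the fences + threshold by a scan
        rng = np.random.default_rng(11)
        base = rng.gamma(2.0, 3.0, size=450)
        extreme = rng.gamma(2.0, 3.0, size=50) + 500.0
        values = np.concatenate([base, extreme])
        x, rep = filter_expression(values, threshold=50, outlier_rule="iqr")
        q1, q3 = np.percentile(values, [25, 75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        scan = [v for v in values if lo <= v <= hi and v <= 50]
        assert sorted(x) == sorted(scan)
        assert rep.retained_fraction == len(scan) / len(values)

    def test_everything_removed_is_an_error(self):
        with pytest.raises(ValueError, match="all values removed"):
            filter_expression([100.0, 200.0], threshold=50, outlier_rule=None)


class TestGofTest:
    def test_normal_sample_accepted(self):
        rng = np.random.default_rng(5)
        res = gof_test(rng.normal(10, 2, size=400), "normal")
        assert res.p_value >= 0.05 and res.compatible

    def test_lognormal_sample_accepted_on_log_scale(self):
        rng = np.random.default_rng(6)
        res = gof_test(np.exp(rng.normal(1, 0.5, size=400)), "lognormal")
        assert res.p_value >= 0.05

    def test_normal_family_rejects_heavy_skew(self):
        rng = np.random.default_rng(7)
        res = gof_test(rng.exponential(5, size=400), "normal")
        assert res.p_value < 0.05 and not res.compatible

    def test_gamma_bootstrap_accepts_gamma_sample(self):
        rng = np.random.default_rng(8)
        res = gof_test(rng.gamma(2.0, 3.0, size=300), "gamma", n_boot=99, seed=1)
        assert res.p_value >= 0.05

    def test_gamma_zeros_excluded_when_flagged(self):
        rng = np.random.default_rng(9)
        values = np.concatenate([rng.gamma(2.0, 3.0, size=200), np.zeros(20)])
        res = gof_test(values, "gamma", exclude_zeros_for_gamma=True,
                       n_boot=49, seed=2)
        assert res.n_used == 200

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gof_test([3.0] * 50, "normal")

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            gof_test([1.0, 2.0, 3.0], "normal")
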