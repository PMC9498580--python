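"""Binomial aggregation statistic and exact 2x2 testing, with brute-force oracles."""

import itertools
from math import comb, prod

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from ciliavar.aggregation import (
    aggregate_variant,
    binomial_point_prob,
    binomial_upper_tail,
    fisher_exact_2x2,
    sex_frequency_test,
)
from ciliavar.errors import ValidationError
from ciliavar.models import Cohort


def pmf_by_path_enumeration(k, n, p):
    """Independent oracle: sum sequence probabilities over all 2^n outcomes."""
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=n):
        if sum(outcome) == k:
            total += prod(p if x else 1.0 - p for x in outcome)
    return total


def fisher_by_enumeration(a, b, c, d):
    """Independent oracle: enumerate all tables with the observed margins."""
    n1, n2, m1, total = a + b, c + d, a + c, a + b + c + d
    if n1 == 0 or n2 == 0 or m1 == 0 or m1 == total:
        return 1.0
    denom = comb(total, m1)

    def prob(x):
        return comb(n1, x) * comb(n2, m1 - x) / denom

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, m1 - n2), min(m1, n1) + 1)
        if prob(x) <= p_obs * (1 + 1e-7)
    )


class TestBinomialPointProb:
    def test_matches_path_enumeration_small_n(self):
        for n in range(1, 11):
            for p in (0.1, 0.5, 0.9):
                for k in range(n + 1):
                    assert binomial_point_prob(k, n, p) == pytest.approx(
                        pmf_by_path_enumeration(k, n, p), abs=1e-12
                    )

    def test_matches_scipy_binom(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0, 1))
            assert binomial_point_prob(k, n, p) == pytest.approx(
                scipy.stats.binom.pmf(k, n, p), rel=1e-10
            )

    def test_zero_successes_closed_form(self):
        for n, p in [(5, 0.1), (22, 0.053), (40, 0.9)]:
            assert binomial_point_prob(0, n, p) == pytest.approx((1 - p) ** n, rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_probabilities(self, p):
        assert binomial_point_prob(0, 5, p) == (1.0 if p == 0.0 else 0.0)
        assert binomial_point_prob(5, 5, p) == (0.0 if p == 0.0 else 1.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n=st.integers(min_value=1, max_value=50),
        p=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    )
    def test_pmf_sums_to_one(self, n, p):
        total = sum(binomial_point_prob(k, n, p) for k in range(n + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            binomial_point_prob(5, 3, 0.5)
        with pytest.raises(ValidationError):
            binomial_point_prob(1, 3, 1.5)
        with pytest.raises(ValidationError):
            binomial_point_prob(-1, 3, 0.5)


class TestBinomialUpperTail:
    def test_full_support_is_one(self):
        for n, p in [(1, 0.3), (22, 0.053), (50, 0.9)]:
            assert binomial_upper_tail(0, n, p) == pytest.approx(1.0, abs=1e-12)

    def test_single_term_tail(self):
        assert binomial_upper_tail(7, 7, 0.4) == pytest.approx(0.4**7, rel=1e-12)

    def test_complement_identity_at_study_point(self):
        k, n, p = 2, 22, 0.0530
        expected = 1.0 - binomial_point_prob(0, n, p) - binomial_point_prob(1, n, p)
        assert binomial_upper_tail(k, n, p) == pytest.approx(expected, rel=1e-12)

    def test_tail_dominates_point_mass(self):
        for k in range(23):
            assert binomial_upper_tail(k, 22, 0.1) >= binomial_point_prob(k, 22, 0.1)


class TestFisherExact:
    def test_symmetric_table_is_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_five_table(self):
        # 6 tables share margins (5,5)/(5,5); only the two diagonal extremes
        # are as unlikely as observed: p = 2/252
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252, rel=1e-9)

    @pytest.mark.parametrize(
        "table", [[[0, 0], [3, 4]], [[0, 5], [0, 2]], [[3, 4], [0, 0]]]
    )
    def test_degenerate_margins_give_one(self, table):
        assert fisher_exact_2x2(table) == 1.0

    def test_matches_enumeration_for_all_small_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
            if a + b + c + d > 40:
                continue
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                fisher_by_enumeration(a, b, c, d), rel=1e-7, abs=1e-12
            )

    def test_matches_scipy_two_sided(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            ours = fisher_exact_2x2([[a, b], [c, d]])
            theirs = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(abcd=st.tuples(*[st.integers(min_value=0, max_value=12)] * 4))
    def test_invariant_under_transposition_and_row_column_swap(self, abcd):
        a, b, c, d = abcd
        p = fisher_exact_2x2([[a, b], [c, d]])
        assert fisher_exact_2x2([[a, c], [b, d]]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_2x2([[d, c], [b, a]]) == pytest.approx(p, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[-1, 1], [1, 1]])

    def test_sex_frequency_test_wraps_fisher(self):
        res = sex_frequency_test(3, 7, 1, 9)
        assert res.p_value == pytest.approx(
            fisher_exact_2x2([[3, 1], [7, 9]]), rel=1e-12
        )


class TestAggregateVariant:
    def test_recurrent_autosomal_variant(self, study_tables, study_cohort):
        records = [
            r
            for r in study_tables["motile"]
            if r.gene == "DNAH9" and r.nt_change == "c.3050A>G"
        ]
        res = aggregate_variant(records, study_cohort)
        assert (res.k, res.n) == (2, 22)
        assert res.p_ref == pytest.approx(0.0530)
        assert res.point_prob == pytest.approx(0.218, abs=5e-4)
        assert res.tail_prob > res.point_prob
        assert res.mode_used == "point" and res.computable

    def test_homozygote_rich_variant_below_significance(
        self, study_tables, study_cohort
    ):
        records = [
            r for r in study_tables["ciliogenesis_trafficking"] if r.gene == "PIBF1"
        ]
        res = aggregate_variant(records, study_cohort)
        assert (res.k, res.n) == (5, 22)
        assert res.point_prob < 0.05

    def test_novel_variant_is_explicitly_not_computable(
        self, study_tables, study_cohort
    ):
        records = [r for r in study_tables["motile"] if r.gene == "HYDIN"]
        res = aggregate_variant(records, study_cohort)
        assert not res.computable and res.novel
        assert "novel" in res.reason
        assert (res.k, res.n) == (2, 22)  # homozygote: dose 2
        assert res.headline is None

    def test_single_patient_cohort(self):
        from ciliavar.models import PredictorProfile, VariantRecord

        record = VariantRecord(
            patient_id="P1",
            gene="DNAH9",
            dbsnp="rs1",
            nt_change="c.1A>G",
            consequence="missense",
            predictors=PredictorProfile(sift_label="D", ma_label="M"),
            allele_freq=0.01,
            zygosity="het",
            panel="motile",
            clinical_class="VUS",
            inheritance="AR",
        )
        cohort = Cohort(patients=(("P1", "male"),))
        res = aggregate_variant([record], cohort)
        assert (res.k, res.n) == (1, 2)

    def test_upper_tail_mode_headline(self, study_tables, study_cohort):
        records = [
            r
            for r in study_tables["motile"]
            if r.gene == "DNAH9" and r.nt_change == "c.3050A>G"
        ]
        res = aggregate_variant(records, study_cohort, mode="upper_tail")
        assert res.headline == res.tail_prob
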