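"""Heterogeneity scores, diversity indices and the normality classifier."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ith_niche.heterogeneity import (
    bin_values,
    dagostino_pearson,
    inverse_simpson_index,
    max_mu_score,
    sd_score,
    shannon_index,
    subgroup_compare,
)

count_vectors = st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=25).filter(
    lambda c: sum(c) > 0
)


def brute_shannon(counts):
    total = sum(counts)
    return -sum((c / total) * math.log(c / total) for c in counts if c > 0)


def brute_inverse_simpson(counts):
    total = sum(counts)
    return 1.0 / sum((c / total) ** 2 for c in counts if c > 0)


class TestScores:
    def test_sd_examples(self):
        assert sd_score([10, 10, 10]) == 0.0
        assert sd_score([0, 10]) == pytest.approx(math.sqrt(50), abs=1e-4)
        with pytest.raises(ValueError):
            sd_score([5.0])

    def test_max_mu_examples(self):
        assert max_mu_score([5, 5, 5]) == 0.0
        assert max_mu_score([0, 0, 10]) == pytest.approx(10 - 10 / 3, abs=1e-4)
        assert max_mu_score([7.3]) == 0.0
        with pytest.raises(ValueError):
            max_mu_score([])

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=40), st.randoms())
    def test_scores_invariant_to_square_order(self, values, rnd):
        shuffled = values[:]
        rnd.shuffle(shuffled)
        assert sd_score(values) == pytest.approx(sd_score(shuffled), rel=1e-12)
        assert max_mu_score(values) == pytest.approx(max_mu_score(shuffled), rel=1e-12)


class TestBinning:
    def test_five_percent_bins_define_twenty_categories(self):
        counts = bin_values([50.0], range_max=100.0, bin_width=5.0)
        assert len(counts) == 20

    def test_half_open_convention(self):
        counts = bin_values([0.0, 4.9, 5.0], range_max=100.0, bin_width=5.0)
        assert counts[0] == 2 and counts[1] == 1

    def test_last_bin_closed_at_range_max(self):
        counts = bin_values([100.0], range_max=100.0, bin_width=5.0)
        assert counts[-1] == 1

    def test_empty_values_give_all_zero_counts(self):
        assert bin_values([], 100.0, 5.0).sum() == 0

    def test_out_of_range_warns_into_end_bin(self):
        with pytest.warns(UserWarning):
            counts = bin_values([105.0], 100.0, 5.0)
        assert counts[-1] == 1

    def test_nonpositive_width_fails(self):
        with pytest.raises(ValueError):
            bin_values([1.0], 100.0, 0.0)

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=50))
    def test_counts_sum_to_n(self, values):
        assert bin_values(values, 100.0, 5.0).sum() == len(values)


class TestDiversityIndices:
    def test_shannon_examples(self):
        assert shannon_index([7]) == 0.0
        assert shannon_index([3, 3, 3, 3]) == pytest.approx(math.log(4), abs=1e-4)
        assert shannon_index([5] * 20) == pytest.approx(math.log(20), abs=1e-4)

    def test_inverse_simpson_examples(self):
        assert inverse_simpson_index([9]) == 1.0
        assert inverse_simpson_index([4] * 7) == pytest.approx(7.0)
        assert inverse_simpson_index([2, 1, 1]) == pytest.approx(1 / 0.375, abs=1e-4)

    def test_bias_corrected_form(self):
        # 1 / [sum n_i(n_i-1) / (N(N-1))] on counts [2,2]: 1/(4/12) = 3
        assert inverse_simpson_index([2, 2], bias_corrected=True) == pytest.approx(3.0)

    @given(count_vectors)
    def test_shannon_agrees_with_brute_force(self, counts):
        assert shannon_index(counts) == pytest.approx(brute_shannon(counts), abs=1e-10)

    @given(count_vectors)
    def test_inverse_simpson_agrees_with_brute_force(self, counts):
        assert inverse_simpson_index(counts) == pytest.approx(
            brute_inverse_simpson(counts), rel=1e-10
        )

    @given(count_vectors)
    def test_empty_category_changes_neither_index(self, counts):
        padded = list(counts) + [0]
        assert shannon_index(padded) == shannon_index(counts)
        assert inverse_simpson_index(padded) == inverse_simpson_index(counts)

    @given(count_vectors)
    def test_index_bounds(self, counts):
        s_occ = sum(1 for c in counts if c > 0)
        assert 0 <= shannon_index(counts) <= math.log(s_occ) + 1e-9
        assert 1 - 1e-9 <= inverse_simpson_index(counts) <= s_occ + 1e-9

    def test_all_zero_counts_fail(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])
        with pytest.raises(ValueError):
            inverse_simpson_index([0, 0])


class TestNormalityClassifier:
    def test_type_one_error_near_nominal(self, rng):
        samples = rng.standard_normal((500, 150))
        rejections = sum(dagostino_pearson(s)[2] for s in samples)
        assert 0.02 < rejections / 500 < 0.09

    def test_bimodal_samples_classified_heterogeneous(self, rng):
        for _ in range(20):
            x = np.concatenate([rng.normal(0, 1, 75), rng.normal(8, 1, 75)])
            k2, p, het = dagostino_pearson(x)
            assert het and p < 0.05

    def test_small_sample_fails(self):
        with pytest.raises(ValueError, match="n >= 8"):
            dagostino_pearson([1.0, 2.0, 3.0, 4.0, 5.0])

    def test_zero_variance_fails(self):
        with pytest.raises(ValueError, match="zero-variance"):
            dagostino_pearson([5.0] * 30)


class TestSubgroupCompare:
    def test_null_distributions_rarely_significant(self, rng):
        hits = 0
        for _ in range(50):
            values = rng.normal(10, 3, 30)
            labels = np.repeat(["pT1M0", "pT1M1", "pT3/4"], 10)
            _, p = subgroup_compare(values, labels)
            hits += p < 0.05
        assert hits / 50 <= 0.10

    def test_shifted_groups_detected(self, rng):
        hits = 0
        for _ in range(40):
            a = rng.normal(0, 1, 10)
            b = rng.normal(3, 1, 10)
            c = rng.normal(6, 1, 10)
            values = np.concatenate([a, b, c])
            labels = np.repeat(["g1", "g2", "g3"], 10)
            _, p = subgroup_compare(values, labels)
            hits += p < 0.05
        assert hits / 40 >= 0.95

    def test_two_groups_use_mann_whitney(self, rng):
        values = np.concatenate([rng.normal(0, 1, 12), rng.normal(5, 1, 12)])
        labels = np.repeat(["low", "high"], 12)
        _, p = subgroup_compare(values, labels)
        assert p < 0.01

    def test_degenerate_groups_fail(self):
        with pytest.raises(ValueError):
            subgroup_compare([1.0, 2.0, 3.0], ["a", "a", "b"])
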