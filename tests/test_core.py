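"""Exact discordance statistics: hand-checked examples and structural invariants."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from hplus import (
    DegeneratePartitionError,
    DissimilarityMatrix,
    InputError,
    PartitionLabels,
    alpha_from_balance,
    count_s,
    discordance,
    expected_g_plus,
    g_plus,
    h_plus,
    penalized_h_plus,
    split_distances,
)
from hplus.core import count_s_brute_force

from conftest import random_labelled_instance


class TestSplitDistances:
    def test_hand_example(self, hand_example):
        D, labels = hand_example
        split = split_distances(D, labels)
        assert split.within.tolist() == [1.0]
        assert sorted(split.between.tolist()) == [5.0, 6.0]
        assert split.alpha == pytest.approx(1 / 3)
        assert split.n_distances == 3

    def test_single_pair_same_label(self):
        D = DissimilarityMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]))
        split = split_distances(D, ["A", "A"])
        assert split.n_within == 1 and split.n_between == 0
        assert split.alpha == 1.0

    def test_length_mismatch(self, hand_example):
        D, _ = hand_example
        with pytest.raises(InputError, match="length"):
            split_distances(D, ["A", "B"])

    def test_sizes_always_sum_to_n_distances(self, rng):
        for _ in range(20):
            D, labels = random_labelled_instance(rng)
            split = split_distances(D, labels)
            assert split.n_within + split.n_between == D.n_distances


class TestCountS:
    @pytest.mark.parametrize(
        "within,between,expected,ties",
        [
            ([3, 1], [2], 1, 0),
            ([1, 2], [3, 4], 0, 0),
            ([5], [5], 0, 1),  # strict inequality: a tie contributes nothing
            ([], [1, 2], 0, 0),
            ([1, 2], [], 0, 0),
        ],
    )
    def test_examples(self, within, between, expected, ties):
        s, t = count_s(within, between, return_ties=True)
        assert s == expected
        assert t == ties

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            D, labels = random_labelled_instance(rng, max_n=25)
            split = split_distances(D, labels)
            assert count_s(split.within, split.between) == count_s_brute_force(
                split.within, split.between
            )

    def test_matches_mannwhitney_u(self, rng):
        # the strict-exceedance count is the Mann-Whitney U statistic on
        # tie-free data; scipy is the independent reference
        for _ in range(20):
            w = rng.normal(0.2, 1, size=rng.integers(2, 40))
            b = rng.normal(0.0, 1, size=rng.integers(2, 40))
            u = scipy.stats.mannwhitneyu(w, b, alternative="two-sided").statistic
            assert count_s(w, b) == int(u)

    @given(
        w=st.lists(st.integers(0, 8), max_size=30),
        b=st.lists(st.integers(0, 8), max_size=30),
    )
    @settings(deadline=None, derandomize=True, max_examples=150)
    def test_bruteforce_equivalence_property(self, w, b):
        s, ties = count_s(w, b, return_ties=True)
        assert s == count_s_brute_force(w, b)
        assert ties == sum(1 for x in w for y in b if x == y)


class TestRatios:
    def test_g_plus_examples(self):
        assert g_plus(1, 3) == pytest.approx(1 / 3)
        assert g_plus(0, 17) == 0.0
        with pytest.raises(InputError):
            g_plus(0, 1)

    def test_h_plus_examples(self):
        assert h_plus(1, 2, 1) == 0.5
        assert h_plus(0, 5, 7) == 0.0

    @pytest.mark.parametrize("nw,nb,side", [(0, 3, "within"), (3, 0, "between")])
    def test_h_plus_degenerate_sides(self, nw, nb, side):
        with pytest.raises(DegeneratePartitionError, match=side):
            h_plus(0, nw, nb)

    def test_h_equals_rescaled_g(self, rng):
        for _ in range(30):
            D, labels = random_labelled_instance(rng)
            res = discordance(D, labels)
            nd = res.n_distances
            assert res.h_plus == pytest.approx(
                res.g_plus * nd * (nd - 1) / (2 * res.n_within * res.n_between)
            )

    def test_complementarity_without_ties(self, rng):
        # continuous draws: P(W>B) + P(B>W) = 1
        for _ in range(20):
            w = rng.normal(size=rng.integers(2, 50))
            b = rng.normal(size=rng.integers(2, 50))
            h_wb = h_plus(count_s(w, b), w.size, b.size)
            h_bw = h_plus(count_s(b, w), b.size, w.size)
            assert h_wb + h_bw == pytest.approx(1.0)

    def test_extremes(self):
        # h=0 iff no within exceeds any between; h=1 iff all do
        assert h_plus(count_s([1, 2], [2, 3]), 2, 2) == 0.0
        assert h_plus(count_s([4, 5], [1, 3]), 2, 2) == 1.0

    def test_bounds(self, rng):
        for _ in range(30):
            D, labels = random_labelled_instance(rng)
            res = discordance(D, labels)
            assert 0.0 <= res.h_plus <= 1.0
            assert 0.0 <= res.g_plus <= 1.0
            assert res.s <= res.n_within * res.n_between


class TestDiscordance:
    def test_hand_example(self, hand_example):
        D, labels = hand_example
        res = discordance(D, labels)
        assert res.s == 0  # 1 < 5 and 1 < 6
        assert res.g_plus == 0.0
        assert res.h_plus == 0.0
        assert res.alpha == pytest.approx(1 / 3)
        assert res.ties == 0

    def test_label_renaming_invariance(self, rng):
        D, labels = random_labelled_instance(rng)
        renamed = ["grp-%d" % (9 - c) for c in labels.codes]
        assert discordance(D, labels) == discordance(D, renamed)

    def test_single_cluster_raises_with_partial(self, hand_example):
        D, _ = hand_example
        with pytest.raises(DegeneratePartitionError) as err:
            discordance(D, ["A", "A", "A"])
        assert err.value.partial["s"] == 0
        assert err.value.partial["g_plus"] == 0.0
        assert err.value.partial["alpha"] == 1.0

    def test_all_singletons_raises(self, hand_example):
        D, _ = hand_example
        with pytest.raises(DegeneratePartitionError):
            discordance(D, ["A", "B", "C"])

    def test_tie_diagnostic(self):
        D = DissimilarityMatrix.from_condensed([2.0, 2.0, 2.0])
        res = discordance(D, ["A", "A", "B"])
        assert res.s == 0
        assert res.ties == 2  # the single within value equals both betweens


class TestAlphaFromBalance:
    def test_imbalanced_thousand(self):
        # 900/100 split: (900*899/2 + 100*99/2) / (1000*999/2) = 819/999
        assert alpha_from_balance(1000, [0.9, 0.1]) == pytest.approx(819 / 999)
        assert round(alpha_from_balance(1000, [0.9, 0.1]), 2) == 0.82

    def test_balanced_thousand(self):
        assert alpha_from_balance(1000, [0.5, 0.5]) == pytest.approx(499 / 999)

    def test_single_group(self):
        assert alpha_from_balance(50, [1.0]) == pytest.approx(1.0)

    def test_matches_empirical_alpha_exactly(self, rng):
        for _ in range(30):
            D, labels = random_labelled_instance(rng)
            split = split_distances(D, labels)
            assert alpha_from_balance(labels.n, labels.balance) == pytest.approx(
                split.alpha, abs=1e-12
            )

    def test_errors(self):
        with pytest.raises(InputError):
            alpha_from_balance(1, [1.0])
        with pytest.raises(InputError):
            alpha_from_balance(10, [0.6, 0.6])
        with pytest.raises(InputError):
            alpha_from_balance(10, [1.2, -0.2])


class TestExpectedGPlus:
    def test_null_values(self):
        nd = 1000 * 999 // 2
        assert expected_g_plus(0.5, nd, 0.5) == pytest.approx(0.25, abs=1e-5)
        assert expected_g_plus(0.82, nd, 0.5) == pytest.approx(0.1476, abs=1e-3)
        assert expected_g_plus(0.0, nd, 0.5) == 0.0
        assert expected_g_plus(1.0, nd, 0.5) == 0.0

    def test_small_sample_factor(self):
        # N_d/(N_d-1) inflates the large-sample value at tiny N_d
        assert expected_g_plus(0.5, 2, 0.5) == pytest.approx(0.5)

    def test_errors(self):
        with pytest.raises(InputError):
            expected_g_plus(0.5, 1, 0.5)
        with pytest.raises(InputError):
            expected_g_plus(1.5, 10, 0.5)


class TestPenalizedHPlus:
    def test_values(self):
        assert penalized_h_plus(0.5, 0.5, "max") == 1.0
        assert penalized_h_plus(0.5, 0.5, "min") == 1.0
        assert penalized_h_plus(0.5, 0.9, "max") == pytest.approx(0.5 / 0.9)
        assert penalized_h_plus(0.5, 0.9, "min") == pytest.approx(5.0)  # may exceed 1

    def test_errors(self):
        with pytest.raises(DegeneratePartitionError):
            penalized_h_plus(0.5, 1.0, "max")
        with pytest.raises(InputError):
            penalized_h_plus(0.5, 0.5, "median")


class TestDissimilarityMatrix:
    def test_symmetrizes_within_tolerance(self):
        M = np.array([[0.0, 1.0], [1.0 + 1e-12, 0.0]])
        D = DissimilarityMatrix(M)
        assert D.values[0, 1] == D.values[1, 0]

    def test_rejects_gross_asymmetry(self):
        with pytest.raises(InputError, match="asymmetric"):
            DissimilarityMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(InputError, match="diagonal"):
            DissimilarityMatrix(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_rejects_nonfinite_and_tiny(self):
        with pytest.raises(InputError):
            DissimilarityMatrix(np.array([[0.0, np.nan], [np.nan, 0.0]]))
        with pytest.raises(InputError):
            DissimilarityMatrix(np.zeros((1, 1)))

    def test_condensed_round_trip(self, rng):
        from conftest import random_dissimilarity

        D = random_dissimilarity(rng, 8)
        again = DissimilarityMatrix.from_condensed(D.condensed())
        np.testing.assert_array_equal(D.values, again.values)

    def test_condensed_bad_length(self):
        with pytest.raises(InputError, match="triangular"):
            DissimilarityMatrix.from_condensed([1.0, 2.0, 3.0, 4.0])


class TestPartitionLabels:
    def test_balance_and_counts(self):
        labels = PartitionLabels(["b", "a", "b", "b"])
        assert labels.k == 2
        assert labels.counts.tolist() == [3, 1]  # first-appearance order
        assert labels.balance.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            PartitionLabels([])
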