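"""Generalized pairwise comparisons: scoring, net benefit, inference."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from crossbench import (GPCConfig, conditional_sign_test, net_benefit_matched,
                        net_benefit_unmatched, permutation_test_unmatched,
                        score_pair, score_pair_nonprioritized,
                        score_pair_prioritized)

from conftest import dataset_from_blocks


class TestScorePair:
    @pytest.mark.parametrize("v1,v2,direction,expected", [
        (5, 3, "higher_is_better", 1),    # raw convention: V1 > V2 wins
        (4, 4, "higher_is_better", 0),    # ties are first-class
        (3, 5, "lower_is_better", 1),     # fewer blisters on verum: a win
        (5, 3, "lower_is_better", -1),
    ])
    def test_orientation(self, v1, v2, direction, expected):
        assert score_pair(v1, v2, direction) == expected

    def test_prioritized_ladder_descends_on_ties(self):
        # t3 ties (3=3), decided at t4: 3 vs 1, lower is better -> loss
        s = score_pair_prioritized((2, 4, 3, 3), (5, 4, 3, 1),
                                   priority_order=(3, 4, 2, 1),
                                   direction="lower_is_better")
        assert s == -1

    def test_prioritized_identical_blocks_tie(self):
        assert score_pair_prioritized((1, 2, 3, 4), (1, 2, 3, 4)) == 0

    def test_prioritized_decided_at_last_rung(self):
        # blocks differ only at t1, the lowest priority
        s = score_pair_prioritized((9, 5, 5, 5), (1, 5, 5, 5),
                                   priority_order=(3, 4, 2, 1),
                                   direction="lower_is_better")
        assert s == -1

    @pytest.mark.parametrize("b1,b2,expected", [
        ((1, 1, 1, 1), (2, 2, 2, 2), 1.0),        # unanimous wins
        ((1, 2, 9, 9), (2, 1, 9, 9), 0.0),        # (+1 - 1 + 0 + 0) / 4
        ((3, 3, 3, 3), (3, 3, 3, 3), 0.0),
    ])
    def test_nonprioritized_average(self, b1, b2, expected):
        assert score_pair_nonprioritized(b1, b2, "lower_is_better") == \
            pytest.approx(expected)


class TestNetBenefit:
    def test_unmatched_univariate_hand_example(self):
        # summaries (t3 - t1): verum {3, 5, 7}, placebo {5, 6, 2}
        d = dataset_from_blocks(
            placebo_blocks=[(0, 0, 5, 0), (0, 0, 6, 0), (0, 0, 2, 0)],
            verum_blocks=[(0, 0, 3, 0), (0, 0, 5, 0), (0, 0, 7, 0)])
        res = net_benefit_unmatched(d, GPCConfig(comparison="univariate"))
        assert (res.wins, res.losses, res.ties) == (3, 5, 1)
        assert res.n_pairs == 9
        assert res.delta == pytest.approx(-2.0 / 9.0)

    def test_dominant_arm_reaches_plus_one(self):
        d = dataset_from_blocks(placebo_blocks=[(9, 9, 9, 9)] * 3,
                                verum_blocks=[(1, 1, 1, 1)] * 3)
        for comparison in ("univariate", "prioritized", "nonprioritized"):
            cfg = GPCConfig(comparison=comparison, summary="total")
            assert net_benefit_unmatched(d, cfg).delta == 1.0
            assert net_benefit_matched(d, cfg).delta == 1.0

    def test_identical_arms_are_null(self, tiny_dataset):
        blocks = tiny_dataset.block_matrix("count")
        placebo = blocks[::2]
        d = dataset_from_blocks(placebo, placebo)
        for comparison in ("univariate", "prioritized", "nonprioritized"):
            cfg = GPCConfig(comparison=comparison)
            assert net_benefit_unmatched(d, cfg).delta == 0.0
            assert net_benefit_matched(d, cfg).delta == 0.0

    def test_matched_counts_subjects_not_pairs(self, null_dataset):
        res = net_benefit_matched(null_dataset, GPCConfig())
        assert res.n_pairs == 15
        assert res.wins + res.losses + res.ties == 15

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_arm_swap_negates_delta_and_accounting_holds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        a = rng.integers(0, 6, size=(n, 4))
        b = rng.integers(0, 6, size=(n, 4))
        d_ab = dataset_from_blocks(a, b)
        d_ba = dataset_from_blocks(b, a)
        for comparison in ("univariate", "prioritized", "nonprioritized"):
            cfg = GPCConfig(comparison=comparison)
            r1 = net_benefit_unmatched(d_ab, cfg)
            r2 = net_benefit_unmatched(d_ba, cfg)
            assert r1.delta == pytest.approx(-r2.delta)
            assert -1.0 <= r1.delta <= 1.0
            assert r1.wins + r1.losses + r1.ties == r1.n_pairs == n * n
            if comparison != "nonprioritized":
                assert r1.delta == pytest.approx(
                    (r1.wins - r1.losses) / r1.n_pairs)

    def test_mann_whitney_linear_transform(self):
        """Univariate unmatched GPC is a linear transform of the
        tie-adjusted Mann-Whitney statistic: Delta = 2U/n^2 - 1."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(2, 10))
            a = rng.integers(0, 5, size=(n, 4))
            b = rng.integers(0, 5, size=(n, 4))
            d = dataset_from_blocks(a, b)
            cfg = GPCConfig(comparison="univariate", summary="total",
                            direction="higher_is_better")
            res = net_benefit_unmatched(d, cfg)
            verum = b.sum(axis=1)
            placebo = a.sum(axis=1)
            U = stats.mannwhitneyu(verum, placebo,
                                   alternative="two-sided").statistic
            assert res.delta == pytest.approx(2 * U / n ** 2 - 1)


class TestPermutationTest:
    def test_degenerate_data_gives_p_one(self):
        d = dataset_from_blocks([(3, 3, 3, 3)] * 4, [(3, 3, 3, 3)] * 4)
        res = permutation_test_unmatched(d, GPCConfig(n_perm=100), seed=0)
        assert res.delta == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("n_subjects", [2, 3, 4])
    def test_exact_test_matches_brute_force(self, n_subjects):
        rng = np.random.default_rng(n_subjects)
        a = rng.integers(0, 8, size=(n_subjects, 4))
        b = rng.integers(0, 8, size=(n_subjects, 4))
        d = dataset_from_blocks(a, b)
        cfg = GPCConfig(comparison="prioritized", exact=True)
        res = permutation_test_unmatched(d, cfg, seed=0)

        # independent brute force over all 2^n within-subject label swaps
        def delta(verum_blocks, placebo_blocks):
            scores = [score_pair_prioritized(v, p)
                      for v in verum_blocks for p in placebo_blocks]
            return np.mean(scores)

        obs = delta(b, a)
        null = []
        for swap in itertools.product((0, 1), repeat=n_subjects):
            v = [a[k] if s else b[k] for k, s in enumerate(swap)]
            p = [b[k] if s else a[k] for k, s in enumerate(swap)]
            null.append(delta(v, p))
        expected = np.mean(np.abs(null) >= abs(obs) - 1e-12)
        assert res.delta == pytest.approx(obs)
        assert res.p_value == pytest.approx(expected)

    def test_sampled_p_is_reproducible(self, null_dataset):
        cfg = GPCConfig(n_perm=300)
        p1 = permutation_test_unmatched(null_dataset, cfg, seed=5).p_value
        p2 = permutation_test_unmatched(null_dataset, cfg, seed=5).p_value
        assert p1 == p2


class TestConditionalSignTest:
    def test_binomial_enumeration_example(self):
        # within-subject scores (+1, +1, +1, 0, -1, 0): m=4, b=3
        d = dataset_from_blocks(
            placebo_blocks=[(5, 5, 5, 5)] * 6,
            verum_blocks=[(4, 4, 4, 4), (3, 3, 3, 3), (2, 2, 2, 2),
                          (5, 5, 5, 5), (6, 6, 6, 6), (5, 5, 5, 5)])
        res = conditional_sign_test(d, GPCConfig(pairing="matched"))
        assert (res.wins, res.losses, res.ties) == (3, 1, 2)
        assert res.p_value == pytest.approx(10 / 16)
        assert res.small_sample_warning  # only 6 matched subjects

    def test_all_ties_give_p_one(self):
        d = dataset_from_blocks([(2, 2, 2, 2)] * 5, [(2, 2, 2, 2)] * 5)
        res = conditional_sign_test(d, GPCConfig(pairing="matched"))
        assert res.p_value == 1.0

    def test_unanimous_fifteen_subjects(self):
        # all 15 scores +1: p = 2 * (1/2)^15 ~ 6.1e-5, no warning at n=15
        placebo = [(6, 6, 6, 6)] * 15
        verum = [(1, 1, 1, 1)] * 15
        res = conditional_sign_test(dataset_from_blocks(placebo, verum),
                                    GPCConfig(pairing="matched"))
        assert res.p_value == pytest.approx(2 * 0.5 ** 15)
        assert not res.small_sample_warning
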