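"""Suffix-tree construction, entropy rate, SIS and derived measures."""

import itertools
import math

import numpy as np
import pytest

from usvsyntax.corpus import LabelAlphabet
from usvsyntax.markov import (
    SuffixTree,
    build_suffix_tree,
    entropy_rate,
    normalized_sis,
    resampled_scores,
    score,
    sis,
    sis_contributions,
    validity_check,
)

from conftest import corpus_from_labels


def brute_force_scores(corpus, depth):
    """Independent oracle: enumerate all (depth+1)-windows directly."""
    windows = []
    for labels in corpus.label_sequences():
        for i in range(len(labels) - depth):
            windows.append(tuple(labels[i : i + depth + 1]))
    n = len(windows)
    from collections import Counter

    joint = Counter(windows)
    suffix = Counter(w[:-1] for w in windows)
    nxt = Counter(w[-1] for w in windows)
    h = 0.0
    for w, c in joint.items():
        p_cond = c / suffix[w[:-1]]
        h -= (suffix[w[:-1]] / n) * p_cond * math.log2(p_cond)
    mi = 0.0
    for w, c in joint.items():
        p = c / n
        q = (suffix[w[:-1]] / n) * (nxt[w[-1]] / n)
        mi += p * math.log2(p / q)
    return h, mi


class TestBuildSuffixTree:
    def test_depth_two_single_window(self):
        corpus = corpus_from_labels([["S", "D", "M"]], LabelAlphabet(("S", "D", "M")))
        tree = build_suffix_tree(corpus, 2)
        assert tree.suffix_counts == {("S", "D"): 1}
        assert tree.cond_counts == {(("S", "D"), "M"): 1}
        assert tree.total_tuples == 1
        # the suffix prints newest-first
        assert SuffixTree.display_suffix(("S", "D")) == "DS"

    def test_depth_zero_counts_label_frequencies(self):
        corpus = corpus_from_labels([["A", "B", "A"], ["B", "B"]])
        tree = build_suffix_tree(corpus, 0)
        assert tree.cond_counts == {((), "A"): 2, ((), "B"): 3}

    def test_alternating_sequence_depth_one(self):
        corpus = corpus_from_labels([["A", "B", "A", "B", "A"]])
        tree = build_suffix_tree(corpus, 1)
        assert tree.suffix_counts == {("A",): 2, ("B",): 2}
        assert tree.cond_counts[(("A",), "B")] == 2
        assert tree.cond_counts[(("B",), "A")] == 2

    def test_windows_never_span_sequences(self):
        corpus = corpus_from_labels([["A", "B"], ["B", "A"]])
        tree = build_suffix_tree(corpus, 1)
        assert tree.total_tuples == 2
        # the cross-sequence pair (B, B) must not be counted
        assert (("B",), "B") not in tree.cond_counts
        short = corpus_from_labels([["A"], ["B"]])
        assert build_suffix_tree(short, 1).total_tuples == 0

    def test_rejects_unlabeled(self):
        corpus = corpus_from_labels([["A", "B"]])
        corpus.sequences[0].syllables[0].label = None
        with pytest.raises(ValueError, match="unlabeled"):
            build_suffix_tree(corpus, 1)

    def test_rejects_excessive_depth(self):
        corpus = corpus_from_labels([["A", "B", "C", "D"]])
        with pytest.raises(ValueError, match="cap"):
            build_suffix_tree(corpus, 30)

    def test_suffix_and_conditional_counts_consistent(self, rng):
        labels = ["".join(rng.choice(list("ABC"), size=rng.integers(2, 12))) for _ in range(30)]
        corpus = corpus_from_labels([list(s) for s in labels], LabelAlphabet(("A", "B", "C")))
        tree = build_suffix_tree(corpus, 2)
        rows = tree.counts.sum(axis=1)
        assert rows.sum() == tree.total_tuples
        for (suf, _), c in tree.cond_counts.items():
            assert c <= tree.suffix_counts[suf]

    def test_json_round_trip(self):
        corpus = corpus_from_labels([["A", "B", "A", "A", "B"]])
        tree = build_suffix_tree(corpus, 1)
        clone = SuffixTree.from_json(tree.to_json())
        assert np.array_equal(clone.counts, tree.counts)
        assert clone.depth == tree.depth


class TestEntropyRate:
    def test_two_label_marginal_entropy(self):
        tree = SuffixTree(0, LabelAlphabet(("J", "N")), np.array([[43, 57]]))
        # H(0.43, 0.57) = 0.9858; the coarser printed value is 0.98
        assert entropy_rate(tree) == pytest.approx(0.9858, abs=5e-4)

    def test_uniform_iid_hits_log2_bound(self):
        tree = SuffixTree(0, LabelAlphabet(tuple("ABCD")), np.full((1, 4), 25))
        assert entropy_rate(tree) == pytest.approx(2.0, abs=1e-12)
        tree1 = SuffixTree(1, LabelAlphabet(tuple("ABCD")), np.full((4, 4), 25))
        assert entropy_rate(tree1) == pytest.approx(2.0, abs=1e-12)

    def test_first_order_chain_plug_in(self, two_state_chain):
        from usvsyntax.ground_truth import analytic_stationary

        mu = analytic_stationary(two_state_chain)
        joint = (mu[:, None] * two_state_chain.cond * 1e9).round()
        tree = SuffixTree(1, two_state_chain.alphabet, joint)
        assert round(entropy_rate(tree), 2) == 0.93

    def test_matches_brute_force(self, rng):
        labels = [list(rng.choice(list("AB"), size=rng.integers(3, 15))) for _ in range(40)]
        corpus = corpus_from_labels(labels, LabelAlphabet(("A", "B")))
        for depth in (0, 1, 2):
            tree = build_suffix_tree(corpus, depth)
            h_oracle, _ = brute_force_scores(corpus, depth)
            assert entropy_rate(tree) == pytest.approx(h_oracle, abs=1e-12)

    def test_rejects_empty(self):
        tree = SuffixTree(1, LabelAlphabet(("A", "B")), np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            entropy_rate(tree)


class TestSis:
    def test_factorized_ensemble_exactly_zero(self):
        tree = SuffixTree(1, LabelAlphabet(("A", "B")), np.array([[5, 5], [5, 5]]))
        assert sis(tree) == 0.0
        assert all(v == 0.0 for v in sis_contributions(tree).values())

    def test_deterministic_repetition_one_bit(self):
        corpus = corpus_from_labels([["A"] * 6, ["B"] * 6], LabelAlphabet(("A", "B")))
        tree = build_suffix_tree(corpus, 1)
        assert sis(tree) == pytest.approx(1.0, abs=1e-12)
        assert normalized_sis(tree) == pytest.approx(1.0, abs=1e-12)

    def test_two_state_chain_value(self, two_state_chain):
        from usvsyntax.ground_truth import analytic_stationary

        mu = analytic_stationary(two_state_chain)
        joint = (mu[:, None] * two_state_chain.cond * 1e9).round()
        tree = SuffixTree(1, two_state_chain.alphabet, joint)
        assert sis(tree) == pytest.approx(0.070, abs=2e-3)

    def test_matches_brute_force(self, rng):
        labels = [list(rng.choice(list("ABC"), size=rng.integers(3, 15))) for _ in range(60)]
        corpus = corpus_from_labels(labels, LabelAlphabet(("A", "B", "C")))
        for depth in (1, 2):
            tree = build_suffix_tree(corpus, depth)
            _, mi_oracle = brute_force_scores(corpus, depth)
            assert sis(tree) == pytest.approx(mi_oracle, abs=1e-12)

    def test_identity_with_marginal_and_conditional_entropy(self, rng):
        labels = [list(rng.choice(list("AB"), size=10)) for _ in range(30)]
        corpus = corpus_from_labels(labels, LabelAlphabet(("A", "B")))
        tree = build_suffix_tree(corpus, 1)
        p_x = tree.counts.sum(axis=0) / tree.total_tuples
        h0 = -(p_x * np.log2(p_x)).sum()
        assert sis(tree) == pytest.approx(h0 - entropy_rate(tree), abs=1e-12)

    def test_rejects_depth_zero(self):
        tree = SuffixTree(0, LabelAlphabet(("A", "B")), np.array([[3, 4]]))
        with pytest.raises(ValueError, match="depth"):
            sis(tree)


class TestSisContributions:
    def test_known_pair_pmf(self):
        counts = np.array([[40, 10], [10, 40]])
        tree = SuffixTree(1, LabelAlphabet(("A", "B")), counts)
        contrib = sis_contributions(tree)
        assert contrib[("A", "A")] == pytest.approx(0.4 * math.log2(0.4 / 0.25), abs=1e-12)
        assert sum(contrib.values()) == pytest.approx(0.278, abs=5e-4)
        # under-represented tuples contribute negatively
        assert contrib[("A", "B")] < 0

    def test_sum_equals_sis(self, rng):
        for depth in (1, 2):
            labels = [list(rng.choice(list("AB"), size=rng.integers(3, 12))) for _ in range(40)]
            corpus = corpus_from_labels(labels, LabelAlphabet(("A", "B")))
            tree = build_suffix_tree(corpus, depth)
            assert sum(sis_contributions(tree).values()) == pytest.approx(sis(tree), abs=1e-9)


class TestValidity:
    def test_all_pairs_observed(self):
        tree = SuffixTree(1, LabelAlphabet(("A", "B")), np.array([[1, 1], [1, 1]]))
        assert validity_check(tree) is True

    def test_quarter_missing_invalid(self):
        tree = SuffixTree(1, LabelAlphabet(("A", "B")), np.array([[1, 1], [1, 0]]))
        assert validity_check(tree) is False

    def test_borderline_fraction_just_over_threshold(self):
        counts = np.ones((64, 8), dtype=int)
        flat = counts.reshape(-1)
        flat[:52] = 0  # 52/512 = 10.16% zeros: not strictly below 10%
        tree = SuffixTree(2, LabelAlphabet(tuple("ABCDEFGH")), flat.reshape(64, 8))
        assert validity_check(tree) is False
        flat[:51] = 1
        flat[51] = 0
        tree2 = SuffixTree(2, LabelAlphabet(tuple("ABCDEFGH")), flat.reshape(64, 8))
        assert validity_check(tree2) is True  # 1/512 zeros


class TestResampledScores:
    def test_single_rep_zero_spread(self):
        corpus = corpus_from_labels([["A", "B", "A"]] * 5)
        rs = resampled_scores(corpus, 1, reps=1, seed=0)
        assert rs.sd2_entropy_rate == 0.0 and rs.sd2_sis == 0.0

    def test_seed_determinism(self):
        corpus = corpus_from_labels([["A", "B", "A", "A"], ["B", "A"], ["A", "A", "B"]] * 4)
        a = resampled_scores(corpus, 1, reps=10, seed=7)
        b = resampled_scores(corpus, 1, reps=10, seed=7)
        assert a == b

    def test_spread_shrinks_with_corpus_size(self, rng):
        from usvsyntax.ground_truth import MarkovGroundTruth, generate_sequences

        model = MarkovGroundTruth.sticky(2, 0.7)
        small = generate_sequences(model, 200, seed=3)
        large = generate_sequences(model, 800, seed=3)
        rs_small = resampled_scores(small, 1, reps=25, seed=0)
        rs_large = resampled_scores(large, 1, reps=25, seed=0)
        assert rs_large.sd2_entropy_rate < rs_small.sd2_entropy_rate

    def test_rejects_bad_fraction(self):
        corpus = corpus_from_labels([["A", "B"]] * 3)
        with pytest.raises(ValueError, match="frac"):
            resampled_scores(corpus, 1, frac=1.5)


class TestScoreSummary:
    def test_summary_fields(self):
        corpus = corpus_from_labels([["A", "A", "B", "A", "B", "B"]] * 3)
        s = score(build_suffix_tree(corpus, 1))
        assert s.depth == 1 and s.n_tuples == 15
        assert 0 <= s.entropy_rate <= 1.0 and s.sis >= 0
        assert s.valid is True

    def test_normalized_sis_eight_labels_divides_by_three(self, rng):
        labels = [list(rng.choice(list("ABCDEFGH"), size=20)) for _ in range(50)]
        corpus = corpus_from_labels(labels, LabelAlphabet(tuple("ABCDEFGH")))
        tree = build_suffix_tree(corpus, 1)
        assert normalized_sis(tree) == pytest.approx(sis(tree) / 3.0, abs=1e-12)

    def test_normalized_sis_rejects_single_label(self):
        tree = SuffixTree(1, LabelAlphabet(("A",)), np.array([[4]]))
        with pytest.raises(ValueError, match="2 labels"):
            normalized_sis(tree)
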