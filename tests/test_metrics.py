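import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from veriset import metrics as vm
from veriset.fixtures import ToyEncoder


# ---------------------------------------------------------------- oracles

def oracle_tokens(text):
    out = []
    word = []
    for ch in text.lower():
        if ch.isalnum():
            word.append(ch)
        else:
            if word:
                out.append("".join(word))
            word = []
    if word:
        out.append("".join(word))
    return out


def oracle_rouge_n(hyp, ref, n):
    """Clipped n-gram recall via explicit list counting."""
    rt, ht = oracle_tokens(ref), oracle_tokens(hyp)
    ref_grams = [tuple(rt[i:i + n]) for i in range(len(rt) - n + 1)]
    hyp_grams = [tuple(ht[i:i + n]) for i in range(len(ht) - n + 1)]
    if not ref_grams:
        return None
    matched = 0
    for gram in set(ref_grams):
        matched += min(ref_grams.count(gram), hyp_grams.count(gram))
    return matched / len(ref_grams)


def oracle_lcs(a, b):
    """Longest common subsequence by exhaustive enumeration (short inputs)."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for r in range(len(short), 0, -1):
        for combo in itertools.combinations(short, r):
            it = iter(long_)
            if all(tok in it for tok in combo):
                return r
    return best


def oracle_rouge_l(hyp, ref, beta=1.0):
    rt, ht = oracle_tokens(ref), oracle_tokens(hyp)
    if not rt or not ht:
        return None
    lcs = oracle_lcs(rt, ht)
    if lcs == 0:
        return 0.0
    r, p = lcs / len(rt), lcs / len(ht)
    return (1 + beta**2) * r * p / (r + beta**2 * p)


def oracle_wilson(s, t, confidence):
    from scipy.stats import norm

    z = norm.ppf(1 - (1 - confidence) / 2)
    p = s / t
    denom = 1 + z**2 / t
    center = (p + z**2 / (2 * t)) / denom
    half = z / denom * math.sqrt(p * (1 - p) / t + z**2 / (4 * t**2))
    return center - half, center + half


WORDS = ["limb", "morphogenesis", "development", "cytosolic", "ribosome",
         "assembly", "signal", "transport", "protein", "response"]


# ----------------------------------------------------------------- ROUGE

class TestRouge:
    def test_identity_scores_one(self):
        text = "cytosolic ribosome assembly"
        assert vm.rouge_n(text, text, 1) == 1.0
        assert vm.rouge_n(text, text, 2) == 1.0
        assert vm.rouge_l(text, text) == 1.0

    def test_disjoint_vocabularies_score_zero(self):
        assert vm.rouge_n("alpha beta", "gamma delta", 1) == 0.0
        assert vm.rouge_l("alpha beta", "gamma delta") == 0.0

    def test_unigram_recall_hand_count(self):
        # 2 of the reference's 3 unigrams appear in the hypothesis
        score = vm.rouge_n("cytosolic ribosome", "cytosolic ribosome assembly", 1)
        assert score == pytest.approx(2 / 3)

    def test_lcs_f_measure_hand_case(self):
        # LCS("limb morphogenesis","limb development") = 1; R = P = 1/2
        assert vm.rouge_l("limb development", "limb morphogenesis") == pytest.approx(0.5)

    def test_reference_shorter_than_n_reported_missing(self):
        assert vm.rouge_n("limb", "limb", 2) is None
        assert vm.rouge_n("limb development", "", 1) is None

    def test_beta_weighting_moves_f_toward_recall(self):
        hyp, ref = "limb", "limb morphogenesis pathway"
        f1 = vm.rouge_l(hyp, ref, vm.RougeConfig(beta=1.0))
        f9 = vm.rouge_l(hyp, ref, vm.RougeConfig(beta=9.0))
        r = 1 / 3  # recall of the 3-token reference
        assert abs(f9 - r) < abs(f1 - r)

    @pytest.mark.parametrize("seed", range(4))
    def test_equivalence_with_independent_oracle_on_random_pairs(self, seed):
        rng = random.Random(seed)
        for _ in range(30):
            hyp = " ".join(rng.choices(WORDS, k=rng.randint(1, 7)))
            ref = " ".join(rng.choices(WORDS, k=rng.randint(1, 7)))
            for n in (1, 2):
                assert vm.rouge_n(hyp, ref, n) == pytest.approx(
                    oracle_rouge_n(hyp, ref, n)
                ), (hyp, ref, n)
            assert vm.rouge_l(hyp, ref) == pytest.approx(
                oracle_rouge_l(hyp, ref)
            ), (hyp, ref)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(st.sampled_from(WORDS), min_size=1, max_size=6).map(" ".join)
    )
    def test_scores_bounded_and_identity_property(self, text):
        assert vm.rouge_n(text, text, 1) == 1.0
        assert vm.rouge_l(text, text) == 1.0
        other = "unrelated tokens entirely"
        for score in (vm.rouge_n(other, text, 1), vm.rouge_l(other, text)):
            assert 0.0 <= score <= 1.0


# ------------------------------------------------------------ similarity

class TestCosineAndSimilarity:
    def test_identical_orthogonal_antiparallel(self):
        u = np.array([1.0, 0.0])
        assert vm.cosine_similarity(u, u) == pytest.approx(1.0)
        assert vm.cosine_similarity(u, np.array([0.0, 1.0])) == pytest.approx(0.0)
        assert vm.cosine_similarity(u, -u) == pytest.approx(-1.0)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            vm.cosine_similarity(np.zeros(3), np.ones(3))

    def test_identical_text_scores_one_under_any_pure_encoder(self, encoder):
        assert vm.semantic_similarity(
            "Limb morphogenesis", "Limb morphogenesis", encoder
        ) == pytest.approx(1.0)

    def test_count_vector_cosine_hand_computed(self, encoder):
        # one shared token of two per phrase: 1 / (sqrt(2) * sqrt(2))
        sim = vm.semantic_similarity("limb morphogenesis", "limb development", encoder)
        assert sim == pytest.approx(0.5)


# ------------------------------------------------------------- percentile

def oracle_percentile(p, gt, terms, encoder):
    """Full sort-and-count: rank all similarities descending and count
    candidates strictly below sim(p, gt)."""
    sims = [vm.semantic_similarity(p, t, encoder) for t in terms]
    sim_gt = vm.semantic_similarity(p, gt, encoder)
    ordered = sorted(sims, reverse=True)
    below = sum(1 for s in ordered if s < sim_gt)
    return 100.0 * below / len(terms)


class TestBackgroundPercentile:
    def test_unique_top_candidate_lands_at_n_minus_one_over_n(self, encoder):
        q = vm.BackgroundSet(
            terms=["limb morphogenesis", "ion transport", "membrane assembly",
                   "protein folding"]
        )
        res = vm.background_percentile(
            "limb morphogenesis", "limb morphogenesis", q, encoder
        )
        assert res.percentile == pytest.approx(100 * 3 / 4)

    def test_ground_truth_below_all_candidates_scores_zero(self, encoder):
        q = vm.BackgroundSet(
            terms=["signal response pathway", "signal transport", "ground truth"]
        )
        res = vm.background_percentile(
            "signal response", "ground truth", q, encoder
        )
        assert res.percentile == 0.0

    def test_empty_background_raises(self, encoder):
        with pytest.raises(ValueError):
            vm.background_percentile("a", "b", vm.BackgroundSet(terms=[]), encoder)

    def test_absent_ground_truth_appended_and_flagged(self, encoder):
        q = vm.BackgroundSet(terms=["ion transport", "protein folding"])
        res = vm.background_percentile("limb morphogenesis", "limb", q, encoder)
        assert res.ground_truth_appended

    @pytest.mark.parametrize("seed", range(5))
    def test_equivalence_with_sort_and_count_oracle(self, seed, encoder):
        rng = random.Random(seed)
        for _ in range(25):
            terms = [
                " ".join(rng.choices(WORDS, k=rng.randint(1, 4)))
                for _ in range(rng.randint(2, 8))
            ]
            gt = rng.choice(terms)
            p = " ".join(rng.choices(WORDS, k=rng.randint(1, 4)))
            q = vm.BackgroundSet(terms=terms)
            res = vm.background_percentile(p, gt, q, encoder)
            assert res.percentile == pytest.approx(
                oracle_percentile(p, gt, terms, encoder)
            )

    def test_monotone_in_ground_truth_similarity(self, encoder):
        """Raising sim(p, ground truth) with the background fixed never
        lowers the percentile."""
        terms = ["ion transport", "membrane assembly", "protein folding",
                 "signal response"]
        p = "limb morphogenesis development"
        gts = ["ribosome", "limb", "limb morphogenesis",
               "limb morphogenesis development"]
        pairs = []
        for gt in gts:
            q = vm.BackgroundSet(terms=terms + [gt])
            res = vm.background_percentile(p, gt, q, encoder)
            pairs.append((res.sim_ground_truth, res.percentile))
        pairs.sort()
        percentiles = [pct for _, pct in pairs]
        assert percentiles == sorted(percentiles)


class TestAssembleBackground:
    def test_sizes_add_exactly(self):
        q = vm.assemble_background(
            [f"go{i}" for i in range(5)], ["n1", "n2"], ["m1"]
        )
        assert len(q) == 8
        assert q.terms[:5] == [f"go{i}" for i in range(5)]

    def test_duplicates_retained(self):
        assert len(vm.assemble_background(["a", "b"], ["b"], [])) == 3

    def test_empty_build_allowed_but_unusable_downstream(self, encoder):
        q = vm.assemble_background([], [], [])
        assert len(q) == 0
        with pytest.raises(ValueError):
            vm.background_percentile("a", "b", q, encoder)


# ------------------------------------------------------ hierarchical

class TestHierarchicalComparison:
    def test_no_ancestors_within_k_means_flag_false(
        self, diamond_tail_graph, encoder
    ):
        res = vm.hierarchical_comparison(
            "term F", "term F", diamond_tail_graph, encoder, k=3
        )
        assert res.ancestor_higher is False
        assert res.best_ancestor is None

    def test_unresolvable_ground_truth_flagged_skipped(
        self, diamond_tail_graph, encoder
    ):
        res = vm.hierarchical_comparison(
            "x", "no such name", diamond_tail_graph, encoder
        )
        assert res.skipped

    def test_flag_matches_exhaustive_comparison_over_all_ancestors(
        self, diamond_tail_graph, encoder
    ):
        from veriset.ontology import ancestors_within_hops

        for predicted in ("term B", "term A", "membrane assembly"):
            res = vm.hierarchical_comparison(
                predicted, "term A", diamond_tail_graph, encoder, k=3
            )
            sims = [
                vm.semantic_similarity(
                    predicted, diamond_tail_graph.name_of(a), encoder
                )
                for a in ancestors_within_hops(diamond_tail_graph, "A", 3)
            ]
            sim_gt = vm.semantic_similarity(predicted, "term A", encoder)
            assert res.ancestor_higher == (bool(sims) and max(sims) > sim_gt)


# ------------------------------------------------------- exact match

class TestExactMatch:
    def test_identical_lists_score_one(self):
        terms = ["Protein localization to peroxisome", "Ion transport"]
        res = vm.exact_match_accuracy(terms, terms)
        assert (res.matched, res.total, res.accuracy) == (2, 2, 1.0)

    def test_word_sets_must_match_entirely(self):
        res = vm.exact_match_accuracy(
            ["peroxisome protein"], ["Protein localization to peroxisome"]
        )
        assert res.matched == 0

    def test_invariant_under_word_order_permutation(self):
        res = vm.exact_match_accuracy(
            ["peroxisome to localization Protein"],
            ["Protein localization to peroxisome"],
        )
        assert res.matched == 1
        strict = vm.exact_match_accuracy(
            ["peroxisome to localization Protein"],
            ["Protein localization to peroxisome"],
            mode="string",
        )
        assert strict.matched == 0

    def test_zero_tested_terms_is_missing_not_zero(self):
        assert vm.exact_match_accuracy([], ["a"]).accuracy is None


# ----------------------------------------------------------- wilson

class TestWilsonInterval:
    def test_reported_agreement_interval(self):
        lower, upper = vm.wilson_interval(124, 132, 0.95)
        assert round(lower, 3) == 0.885
        assert round(upper, 3) == 0.969

    def test_zero_successes_boundary(self):
        lower, _ = vm.wilson_interval(0, 10, 0.95)
        assert lower == pytest.approx(0.0)

    @pytest.mark.parametrize("s,t", [(5, 10), (1, 7), (50, 60), (0, 3)])
    def test_matches_closed_form_oracle(self, s, t):
        assert vm.wilson_interval(s, t, 0.95) == pytest.approx(
            oracle_wilson(s, t, 0.95)
        )

    @pytest.mark.parametrize("s,t", [(5, 10), (30, 40), (1, 100)])
    def test_contains_point_estimate_and_shrinks_with_trials(self, s, t):
        lower, upper = vm.wilson_interval(s, t)
        assert lower <= s / t <= upper
        lower10, upper10 = vm.wilson_interval(10 * s, 10 * t)
        assert (upper10 - lower10) < (upper - lower)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            vm.wilson_interval(5, 0)
        with pytest.raises(ValueError):
            vm.wilson_interval(11, 10)


# ------------------------------------------------------ batch aggregate

class TestBatchAggregate:
    def test_constant_scores_have_zero_sd(self):
        agg = vm.batch_aggregate([0.5] * 40, batch_size=10, n_batches=4, seed=1)
        assert agg.sd == pytest.approx(0.0)
        assert agg.mean == pytest.approx(0.5)

    def test_partition_mean_equals_plain_mean(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 1, size=180)
        agg = vm.batch_aggregate(scores, batch_size=20, n_batches=9, seed=5)
        assert agg.mean == pytest.approx(scores.mean())

    def test_nine_disjoint_batches_hand_computed(self):
        # 9 batches of size 1 partition the vector: batch means are the
        # values themselves, so sd is the sample sd of the vector.
        scores = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        agg = vm.batch_aggregate(scores, batch_size=1, n_batches=9, seed=0)
        assert agg.mean == pytest.approx(5.0)
        assert agg.sd == pytest.approx(np.std(scores, ddof=1))

    def test_batch_size_larger_than_sample_raises(self):
        with pytest.raises(ValueError):
            vm.batch_aggregate([1.0, 2.0], batch_size=3, n_batches=2)


# ---------------------------------------------------------- encoder

class TestToyEncoder:
    def test_embedding_is_deterministic(self):
        e = ToyEncoder()
        assert np.array_equal(e.embed("a b c"), e.embed("a b c"))

    def test_self_cosine_is_one(self, encoder):
        v = encoder.embed("protein transport")
        assert vm.cosine_similarity(v, v) == pytest.approx(1.0)
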