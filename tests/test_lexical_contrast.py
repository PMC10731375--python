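"""Preprocessing, smoothed odds ratios, top-k ranking, co-occurrence
networks and per-word sampling."""

from collections import Counter
from datetime import datetime, timezone

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from lonelytext.lexical_contrast import (GenderedWordStats, cooccurrence_network,
                                         export_network, odds_ratio,
                                         overlap_words, preprocess,
                                         sample_tweets_for_word, slice_period,
                                         top_k_by_or, word_frequencies)


class TestPreprocess:
    @pytest.mark.parametrize("text, expected", [
        ("I'm SO lonely!! 😢 http://t.co/x", ["im", "lonely"]),
        ("", []),
        ("the and of to", []),                      # stopwords only
        ("Quarantine LOCKDOWN!!", ["quarantine", "lockdown"]),
        ("check www.example.com/page now", ["check"]),
    ])
    def test_examples(self, text, expected):
        assert preprocess(text) == expected

    def test_deterministic(self):
        text = "Lonely hearts club & friends!!"
        assert preprocess(text) == preprocess(text)


def _stats(female: dict, male: dict) -> GenderedWordStats:
    return GenderedWordStats(Counter(female), Counter(male))


class TestOddsRatio:
    def test_symmetric_table_is_one(self):
        stats = _stats({"x": 100}, {"x": 100})
        assert odds_ratio("w", stats) == pytest.approx(1.0)

    def test_worked_arithmetic_example(self):
        # Wf(w)=9 of 100, Wm(w)=4 of 100, alpha=1 -> (10*97)/(5*92)
        stats = _stats({"w": 9, "other": 91}, {"w": 4, "other": 96})
        assert odds_ratio("w", stats) == pytest.approx((10 * 97) / (5 * 92))

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            wf, wm = int(rng.integers(0, 50)), int(rng.integers(0, 50))
            rest_f, rest_m = int(rng.integers(0, 500)), int(rng.integers(0, 500))
            alpha = float(rng.uniform(0.25, 4))
            stats = _stats({"w": wf, "rest": rest_f}, {"w": wm, "rest": rest_m})
            expected = ((wf + alpha) * (rest_m + alpha)) / \
                ((wm + alpha) * (rest_f + alpha))
            assert odds_ratio("w", stats, alpha) == pytest.approx(
                expected, rel=1e-12)

    def test_swapping_genders_inverts(self):
        stats = _stats({"w": 9, "o": 91}, {"w": 4, "o": 96})
        swapped = _stats({"w": 4, "o": 96}, {"w": 9, "o": 91})
        assert odds_ratio("w", stats) * odds_ratio("w", swapped) == \
            pytest.approx(1.0)

    def test_or_approaches_one_monotonically_in_alpha(self):
        stats = _stats({"w": 9, "o": 91}, {"w": 4, "o": 96})
        alphas = [0.5, 1, 2, 5, 10, 100, 1000, 10000]
        ors = [odds_ratio("w", stats, a) for a in alphas]
        deviations = [abs(o - 1) for o in ors]
        assert deviations == sorted(deviations, reverse=True)
        assert ors[-1] == pytest.approx(1.0, abs=0.01)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio("w", _stats({}, {}), alpha=0)


class TestWordFrequencies:
    def test_multiplicity_counting(self, make_tweet):
        tweets = [make_tweet(text="lonely lonely", gender="female")]
        stats = word_frequencies(tweets)
        assert stats.wf("lonely") == 2 and stats.total_female == 2

    def test_empty_corpus(self):
        stats = word_frequencies([])
        assert stats.total_female == 0 and stats.total_male == 0

    def test_disjoint_vocabularies(self, make_tweet):
        tweets = [make_tweet(tweet_id=1, text="apple grape", gender="female"),
                  make_tweet(tweet_id=2, text="rocket engine", gender="male")]
        stats = word_frequencies(tweets)
        assert stats.wm("apple") == 0 and stats.wf("rocket") == 0
        assert stats.wf_not("apple") == stats.total_female - stats.wf("apple")


class TestTopK:
    def test_shortfall_returns_all_in_order(self):
        stats = _stats({"aa": 30, "bb": 10, "cc": 20},
                       {"aa": 5, "bb": 10, "cc": 20})
        top = top_k_by_or(stats, k=100, direction="female", min_count=1)
        assert [r.word for r in top] == ["aa", "bb", "cc"]
        assert top[0].odds_ratio > top[1].odds_ratio >= top[2].odds_ratio

    def test_identical_counts_tie_break_lexicographic(self):
        stats = _stats({"zeta": 10, "beta": 10, "filler": 50},
                       {"zeta": 10, "beta": 10, "filler": 50})
        top = top_k_by_or(stats, k=3, direction="female", min_count=1)
        # all ORs are 1; count tie-break ranks filler first, then the
        # equal-count pair adjacently in lexicographic order
        assert [r.word for r in top] == ["filler", "beta", "zeta"]

    def test_min_count_floor_excludes_rare_words(self):
        stats = _stats({"rare": 1, "common": 50, "pad": 100},
                       {"common": 10, "pad": 100})
        words = {r.word for r in top_k_by_or(stats, k=10, direction="female",
                                             min_count=5)}
        assert "rare" not in words and "common" in words

    def test_planted_markers_dominate_top_list(self, marker_setup):
        _, tweets, _, truth = marker_setup
        disc = [t.with_gender(truth.user_gender[t.user.id]) for t in tweets
                if truth.tweet_contaminant[t.id] is None]
        stats = word_frequencies(disc)
        top_f = {r.word for r in top_k_by_or(stats, k=100, direction="female")}
        top_m = {r.word for r in top_k_by_or(stats, k=100, direction="male")}
        female, male = set(truth.female_markers), set(truth.male_markers)
        assert len(female & top_f) / len(female) >= 0.9
        assert len(male & top_m) / len(male) >= 0.9
        assert not female & top_m and not male & top_f


class TestCooccurrence:
    def test_pair_counted_per_tweet(self, make_tweet):
        tweets = [make_tweet(tweet_id=i, text="apple grape juice")
                  for i in range(2)]
        net = cooccurrence_network(tweets, ["apple", "grape"])
        assert net["apple"]["grape"]["weight"] == 2

    def test_never_cooccurring_words_have_no_edge(self, make_tweet):
        tweets = [make_tweet(tweet_id=1, text="apple pie"),
                  make_tweet(tweet_id=2, text="grape jam")]
        net = cooccurrence_network(tweets, ["apple", "grape"])
        assert net.number_of_edges() == 0

    def test_within_tweet_multiplicity_ignored(self, make_tweet):
        tweets = [make_tweet(text="apple apple grape")]
        net = cooccurrence_network(tweets, ["apple", "grape"])
        assert net["apple"]["grape"]["weight"] == 1

    def test_matches_bruteforce_pair_enumeration(self, make_tweet):
        rng = np.random.default_rng(4)
        vocab = [f"word{i}" for i in range(8)]
        tweets = [make_tweet(tweet_id=i,
                             text=" ".join(rng.choice(vocab, size=5)))
                  for i in range(60)]
        listed = vocab[:5]
        net = cooccurrence_network(tweets, listed)
        brute: Counter = Counter()
        for t in tweets:
            present = sorted({w for w in t.text.split() if w in listed})
            for i, a in enumerate(present):
                for b in present[i + 1:]:
                    brute[(a, b)] += 1
        assert {tuple(sorted(e)): d["weight"]
                for *e, d in net.edges(data=True)} == dict(brute)

    def test_no_self_loops(self, make_tweet):
        net = cooccurrence_network([make_tweet(text="apple apple")], ["apple"])
        assert nx.number_of_selfloops(net) == 0


class TestExportNetwork:
    def test_empty_network_exports(self, tmp_path, make_tweet):
        net = cooccurrence_network([], ["apple"])
        net.remove_node("apple")
        path = export_network(net, tmp_path / "empty.graphml")
        assert nx.read_graphml(path).number_of_nodes() == 0

    def test_round_trip_attributes(self, tmp_path, make_tweet):
        tweets = [make_tweet(text="apple grape pear")]
        net = cooccurrence_network(tweets, ["apple", "grape", "pear"])
        net.nodes["apple"]["odds_ratio"] = 2.0
        net.nodes["grape"]["odds_ratio"] = 1.0
        path = export_network(net, tmp_path / "net.graphml")
        back = nx.read_graphml(path)
        assert back.nodes["apple"]["odds_ratio"] == 2.0
        assert back["apple"]["grape"]["weight"] == 1

    def test_node_size_proportional_to_or(self, tmp_path, make_tweet):
        tweets = [make_tweet(text="apple grape")]
        net = cooccurrence_network(tweets, ["apple", "grape"])
        net.nodes["apple"]["odds_ratio"] = 2.0
        net.nodes["grape"]["odds_ratio"] = 1.0
        back = nx.read_graphml(export_network(net, tmp_path / "n.graphml"))
        assert back.nodes["apple"]["size"] / back.nodes["grape"]["size"] == \
            pytest.approx(2.0)

    def test_gexf_format(self, tmp_path, make_tweet):
        net = cooccurrence_network([make_tweet(text="apple grape")],
                                   ["apple", "grape"])
        back = nx.read_gexf(export_network(net, tmp_path / "net.gexf"))
        assert set(back.nodes) == {"apple", "grape"}


class TestSampleTweets:
    def test_fewer_matches_than_n_returns_all(self, make_tweet):
        tweets = [make_tweet(tweet_id=i, text="apple lonely")
                  for i in range(10)]
        assert len(sample_tweets_for_word(tweets, "apple", n=50, seed=1)) == 10

    def test_absent_word_gives_empty_sample(self, make_tweet):
        assert sample_tweets_for_word([make_tweet()], "zzz", seed=0) == []

    def test_same_seed_same_sample(self, make_tweet):
        tweets = [make_tweet(tweet_id=i, text=f"apple w{i}") for i in range(200)]
        a = sample_tweets_for_word(tweets, "apple", n=20, seed=9)
        b = sample_tweets_for_word(tweets, "apple", n=20, seed=9)
        assert [t.id for t in a] == [t.id for t in b]

    def test_gender_restriction(self, make_tweet):
        tweets = [make_tweet(tweet_id=1, text="apple", gender="female"),
                  make_tweet(tweet_id=2, text="apple", gender="male")]
        out = sample_tweets_for_word(tweets, "apple", n=5, seed=0,
                                     gender="female")
        assert [t.id for t in out] == [1]

    def test_inclusion_is_uniform_over_seeds(self, make_tweet):
        """Chi-square goodness of fit on inclusion counts over repeated
        seeded draws does not reject uniformity."""
        tweets = [make_tweet(tweet_id=i, text="apple") for i in range(300)]
        counts = np.zeros(300)
        n_draws, n_keep = 1000, 30
        for seed in range(n_draws):
            for t in sample_tweets_for_word(tweets, "apple", n=n_keep,
                                            seed=seed):
                counts[t.id] += 1
        expected = n_draws * n_keep / 300
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert sps.chi2.sf(chi2, df=299) > 0.01


def test_period_slicing_and_overlap(make_tweet):
    pre_tweet = make_tweet(
        tweet_id=1, when=datetime(2019, 6, 1, tzinfo=timezone.utc))
    lock_tweet = make_tweet(
        tweet_id=2, when=datetime(2020, 4, 1, tzinfo=timezone.utc))
    edge = make_tweet(
        tweet_id=3, when=datetime(2020, 6, 1, 23, tzinfo=timezone.utc))
    assert [t.id for t in slice_period([pre_tweet, lock_tweet, edge], "pre")] == [1]
    assert [t.id for t in
            slice_period([pre_tweet, lock_tweet, edge], "lockdown")] == [2, 3]

    stats = _stats({"aa": 10, "bb": 10}, {"aa": 1, "bb": 1})
    top_a = top_k_by_or(stats, k=1, direction="female", min_count=1)
    top_b = top_k_by_or(stats, k=2, direction="female", min_count=1)
    assert overlap_words(top_a, top_b) == {top_a[0].word}
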