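"""The synthetic corpus generator and its ground truth."""

import math

import pytest

import hookahscope as hs
from hookahscope.synthetic import DEFAULT_TOPIC_RATES


def test_empty_corpus():
    corpus, truth = hs.generate(hs.GeneratorConfig(n_tweets=0, seed=1))
    assert len(corpus) == 0 and truth.per_tweet == {}


def test_zero_rates_plant_no_topics():
    config = hs.GeneratorConfig(n_tweets=50, seed=2,
                                topic_rates={t: 0.0 for t in DEFAULT_TOPIC_RATES},
                                cooccurrence_boosts={})
    _, truth = hs.generate(config)
    assert all(t.topics == frozenset() for t in truth.per_tweet.values())


def test_same_seed_is_byte_identical(tmp_path):
    config = hs.GeneratorConfig(n_tweets=300, seed=5)
    a, _ = hs.generate(config)
    b, _ = hs.generate(config)
    pa = hs.write_corpus(a, tmp_path / "a.jsonl")
    pb = hs.write_corpus(b, tmp_path / "b.jsonl")
    assert pa.read_bytes() == pb.read_bytes()


def test_invalid_probabilities_rejected():
    with pytest.raises(ValueError):
        hs.GeneratorConfig(retweet_rate=1.2)
    with pytest.raises(ValueError):
        hs.GeneratorConfig(topic_rates={"Flavors": -0.1})
    with pytest.raises(ValueError):
        hs.GeneratorConfig(topic_rates={"Not A Topic": 0.5})


def test_every_tweet_contains_collection_term(synth_1200):
    _, corpus, _ = synth_1200
    for rec in corpus:
        assert "hookah" in rec.text.lower()


def test_bot_scores_separate_cleanly(synth_1200):
    _, corpus, truth = synth_1200
    for rec in corpus:
        if truth.per_tweet[rec.tweet_id].is_bot_authored:
            assert rec.bot_score >= 0.9
        else:
            assert rec.bot_score <= 0.1


def test_retweets_carry_prefix_and_non_english_carry_code(synth_1200):
    _, corpus, truth = synth_1200
    for rec in corpus:
        t = truth.per_tweet[rec.tweet_id]
        if t.is_retweet:
            assert rec.text.startswith("RT @")
        elif not t.is_english:
            assert rec.lang not in ("en", "und")


def test_expected_report_satisfies_invariants(synth_1200):
    _, _, truth = synth_1200
    report, matrix = hs.expected_report(truth)
    assert report.corpus_size == len(truth.clean_ids)
    assert report.coverage_count + report.uncovered_count == report.corpus_size
    frame = matrix.frame
    assert (frame.to_numpy() == frame.to_numpy().T).all()
    for topic, count in report.topic_counts.items():
        assert matrix.count(topic, topic) == count
    assert report.topic_counts == truth.planted_counts()


def test_single_pair_overlap_truth():
    from hookahscope.synthetic import GroundTruth, TweetTruth
    truth = GroundTruth(per_tweet={
        "t0": TweetTruth(frozenset({"Flavors", "Dislike of Hookah"}), False, False, True),
    }, topic_names=["Flavors", "Dislike of Hookah"])
    report, matrix = hs.expected_report(truth)
    assert matrix.count("Flavors", "Dislike of Hookah") == 1
    assert report.coverage_percent == 100.0


def test_realized_rates_near_planted_rates():
    """Independent draws: realized clean-subset prevalence within 3 binomial
    standard errors of the planted rate for every topic."""
    config = hs.GeneratorConfig(n_tweets=20000, seed=13, cooccurrence_boosts={})
    _, truth = hs.generate(config)
    n = len(truth.clean_ids)
    counts = truth.planted_counts()
    assert n > 2000
    for topic, rate in config.topic_rates.items():
        se = math.sqrt(rate * (1 - rate) / n)
        assert abs(counts[topic] / n - rate) <= 3 * se, topic


def test_end_to_end_recovery_is_exact(synth_1200, lexicons):
    """Filter -> normalize -> classify reproduces the planted report exactly."""
    _, corpus, truth = synth_1200
    clean, _ = hs.run_filter_chain(corpus)
    normalized = hs.normalize_corpus(clean)
    assignments = hs.classify_corpus(normalized, lexicons)
    got_report = hs.prevalence_report(assignments, len(normalized), lexicons.topic_names)
    got_matrix = hs.overlap_matrix(assignments, topic_names=lexicons.topic_names)
    exp_report, exp_matrix = hs.expected_report(truth)
    assert got_report.to_dict() == exp_report.to_dict()
    assert got_matrix == exp_matrix
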