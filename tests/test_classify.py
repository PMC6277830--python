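"""Rule-based classification, prevalence arithmetic, and the overlap matrix."""

import pandas as pd
import pytest

import hookahscope as hs
from hookahscope.classify import TopicAssignment, read_overlap_tsv, write_assignments
from hookahscope.normalize import NormalizedTweet

from conftest import make_record


def brute_force_classify(tokens, lexicons):
    """Independent oracle: literal whole-token / contiguous-pair scan."""
    tokens = list(tokens)
    labels = set()
    for lx in lexicons:
        for kw in lx.keywords:
            parts = kw.split()
            if len(parts) == 1:
                hit = any(tok == kw for tok in tokens)
            else:
                hit = any(tokens[i] == parts[0] and tokens[i + 1] == parts[1]
                          for i in range(len(tokens) - 1))
            if hit:
                labels.add(lx.topic_name)
                break
    return labels


def test_worked_example_craving_and_beer(lexicons):
    rec = make_record(text="I'm craving hookah and a beer right now")
    assignment = hs.classify_tweet(hs.normalize(rec), lexicons)
    assert assignment.topics == {"Appeal or Abuse Liability", "Polysubstance Use"}


def test_no_keywords_means_empty_label_set(lexicons):
    nt = NormalizedTweet("t", ("zzznoise", "hookah"))
    assignment = hs.classify_tweet(nt, lexicons)
    assert assignment.topics == frozenset() and assignment.matched_keywords == {}


def test_mention_party_saturday(lexicons):
    rec = make_record(text="@username hookah party saturday")
    assignment = hs.classify_tweet(hs.normalize(rec), lexicons)
    assert assignment.topics == {"Person Tagging", "Promotional or Social Events"}
    assert assignment.matched_keywords["Promotional or Social Events"] == ["party", "saturday"]


def test_matching_is_whole_token_not_substring(lexicons):
    # "hit" must not fire inside "white"; "mint" not inside "minty"
    assert hs.classify_tweet(NormalizedTweet("t", ("white", "minty")), lexicons).topics == frozenset()


def test_bigram_requires_contiguity(lexicons):
    assert "Dislike of Hookah" in hs.classify_tweet(
        NormalizedTweet("a", ("dont", "hookah")), lexicons).topics
    assert hs.classify_tweet(
        NormalizedTweet("b", ("dont", "ever", "hookah")), lexicons).topics == frozenset()


def test_corpus_classification_matches_brute_force_oracle(clean_normalized, lexicons):
    assignments = hs.classify_corpus(clean_normalized, lexicons)
    assert len(assignments) == len(clean_normalized)
    for nt, assignment in zip(clean_normalized, assignments):
        assert set(assignment.topics) == brute_force_classify(nt.tokens, lexicons)


def test_corpus_order_independence(clean_normalized, lexicons):
    fwd = {a.tweet_id: a.topics for a in hs.classify_corpus(clean_normalized, lexicons)}
    rev = {a.tweet_id: a.topics
           for a in hs.classify_corpus(list(reversed(clean_normalized)), lexicons)}
    assert fwd == rev


def test_adding_keyword_is_monotone(clean_normalized, lexicons):
    """A new keyword can only grow its own topic's count."""
    base = hs.prevalence_report(hs.classify_corpus(clean_normalized, lexicons),
                                len(clean_normalized), lexicons.topic_names)
    grown = hs.apply_review(lexicons, [])
    # pick a token that actually occurs in the corpus
    token = next(t for nt in clean_normalized for t in nt.tokens if t.isalpha())
    grown["Flavors"].keywords.add(token)
    after = hs.prevalence_report(hs.classify_corpus(clean_normalized, grown),
                                 len(clean_normalized), grown.topic_names)
    for topic in lexicons.topic_names:
        if topic == "Flavors":
            assert after.topic_counts[topic] >= base.topic_counts[topic]
        else:
            assert after.topic_counts[topic] == base.topic_counts[topic]


def test_round_percent_half_up():
    assert hs.round_percent(1, 800) == 0.13  # 0.125 rounds up, not to even
    assert hs.round_percent(0, 5) == 0.0
    assert hs.round_percent(5, 5) == 100.0
    with pytest.raises(ValueError):
        hs.round_percent(1, 0)


def test_prevalence_report_identities(clean_normalized, lexicons):
    assignments = hs.classify_corpus(clean_normalized, lexicons)
    report = hs.prevalence_report(assignments, len(assignments), lexicons.topic_names)
    assert report.coverage_count + report.uncovered_count == report.corpus_size
    assert report.coverage_count <= sum(report.topic_counts.values()) or \
        all(len(a.topics) <= 1 for a in assignments)
    ranked = report.ranked_topics()
    counts = [c for _, c, _ in ranked]
    assert counts == sorted(counts, reverse=True)


def test_overlap_matrix_single_multilabel_tweet():
    a = TopicAssignment("t", frozenset({"A", "B"}))
    m = hs.overlap_matrix([a], topic_names=["A", "B", "C"])
    assert m.count("A", "A") == m.count("B", "B") == m.count("A", "B") == m.count("B", "A") == 1
    assert m.count("C", "C") == 0 and m.count("A", "C") == 0


def test_overlap_matrix_properties(clean_normalized, lexicons):
    assignments = hs.classify_corpus(clean_normalized, lexicons)
    m = hs.overlap_matrix(assignments, topic_names=lexicons.topic_names)
    frame = m.frame
    assert (frame.to_numpy() == frame.to_numpy().T).all()
    for a in lexicons.topic_names:
        for b in lexicons.topic_names:
            if a != b:
                assert m.count(a, b) <= min(m.count(a, a), m.count(b, b))
    # diagonal equals per-topic totals
    report = hs.prevalence_report(assignments, len(assignments), lexicons.topic_names)
    for topic in lexicons.topic_names:
        assert m.count(topic, topic) == report.topic_counts[topic]


def test_overlap_matches_pairwise_counting_oracle(clean_normalized, lexicons):
    assignments = hs.classify_corpus(clean_normalized, lexicons)
    m = hs.overlap_matrix(assignments, topic_names=lexicons.topic_names)
    for a in lexicons.topic_names:
        for b in lexicons.topic_names:
            expected = sum(1 for x in assignments if a in x.topics and b in x.topics)
            assert m.count(a, b) == expected


def test_report_files_roundtrip(tmp_path, clean_normalized, lexicons):
    assignments = hs.classify_corpus(clean_normalized, lexicons)
    report = hs.prevalence_report(assignments, len(assignments), lexicons.topic_names)
    matrix = hs.overlap_matrix(assignments, topic_names=lexicons.topic_names)
    paths = hs.report_to_files(report, matrix, tmp_path / "run")
    assert all(p.exists() for p in paths)
    back = read_overlap_tsv(tmp_path / "run_overlap.tsv")
    assert back == matrix
    tsv = (tmp_path / "run_prevalence.tsv").read_text("utf-8").splitlines()
    assert len(tsv) == 1 + len(lexicons.topic_names) + 2  # header + topics + coverage rows
    write_assignments(assignments, tmp_path / "assignments.jsonl")
    assert len((tmp_path / "assignments.jsonl").read_text("utf-8").splitlines()) == len(assignments)


def test_all_zero_report(tmp_path):
    report = hs.prevalence_report([], corpus_size=10, topic_names=["A"])
    matrix = hs.overlap_matrix([], topic_names=["A"])
    hs.report_to_files(report, matrix, tmp_path / "zero")
    assert report.coverage_percent == 0.0 and report.topic_percent("A") == 0.0
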