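"""Skip-gram embeddings and the lexicon-expansion review round-trip."""

import numpy as np
import pytest

import hookahscope as hs
from hookahscope.expansion import Candidate, CandidateList
from hookahscope.lexicon import EXPANDED, SEED
from hookahscope.normalize import NormalizedTweet


@pytest.fixture(scope="module")
def synonym_corpus():
    """Sentences where "crave" and "want" are used in interchangeable contexts
    while a control token ("ledger") lives in disjoint contexts."""
    rng = np.random.default_rng(3)
    ctx = ["tonight", "lounge", "session", "friend", "vibe", "relax", "chill"]
    far = ["stock", "market", "trade", "price", "chart", "index"]
    sents = []
    for i in range(1200):
        word = "crave" if i % 2 else "want"
        c = [ctx[int(rng.integers(len(ctx)))] for _ in range(4)]
        sents.append(NormalizedTweet(f"s{i}", tuple(c[:2] + [word, "hookah"] + c[2:])))
    for i in range(600):
        c = [far[int(rng.integers(len(far)))] for _ in range(4)]
        sents.append(NormalizedTweet(f"c{i}", tuple(c[:2] + ["ledger"] + c[2:])))
    return sents


@pytest.fixture(scope="module")
def model(synonym_corpus):
    config = hs.EmbeddingConfig(dim=40, window=3, min_count=5, epochs=3, seed=1)
    return hs.train_embeddings(synonym_corpus, config)


def test_min_count_excludes_rare_tokens():
    sents = [NormalizedTweet("a", ("hookah", "night") * 5), NormalizedTweet("b", ("rare",))]
    model = hs.train_embeddings(sents, hs.EmbeddingConfig(dim=8, min_count=5, epochs=1))
    assert "hookah" in model and "rare" not in model


def test_empty_vocabulary_errors():
    with pytest.raises(ValueError, match="vocabulary"):
        hs.train_embeddings([NormalizedTweet("a", ("x", "y"))],
                            hs.EmbeddingConfig(min_count=10, epochs=1, dim=4))
    with pytest.raises(ValueError, match="empty corpus"):
        hs.train_embeddings([], hs.EmbeddingConfig())


def test_same_seed_gives_identical_vectors(synonym_corpus):
    config = hs.EmbeddingConfig(dim=16, window=2, min_count=5, epochs=1, seed=9)
    a = hs.train_embeddings(synonym_corpus, config)
    b = hs.train_embeddings(synonym_corpus, config)
    assert np.array_equal(a.vectors, b.vectors)


def test_shared_context_beats_control(model):
    """Planted co-occurrence oracle: interchangeable tokens end up closer
    than tokens from disjoint contexts."""
    assert model.cosine("crave", "want") > model.cosine("crave", "ledger")
    assert model.cosine("crave", "want") > 0.8


def test_cosine_symmetric(model):
    assert model.cosine("crave", "want") == pytest.approx(model.cosine("want", "crave"))


def test_candidates_recover_planted_synonym(model, lexicons):
    """"crave" sits in the appeal lexicon; its planted synonym "want" is a
    seed too, so drop it from the lexicon and check it is re-proposed."""
    reduced = hs.apply_review(lexicons, [])  # deep copy
    appeal = reduced["Appeal or Abuse Liability"]
    appeal.keywords.discard("want")
    candidates = hs.propose_candidates(model, reduced, top_k=10, min_cosine=0.3)
    appeal_rows = next(c for c in candidates if c.topic_name == "Appeal or Abuse Liability")
    proposed = {row.candidate for row in appeal_rows.rows}
    assert "want" in proposed


def test_candidates_exclude_existing_members_and_stopwords(model, lexicons):
    candidates = hs.propose_candidates(model, lexicons, top_k=20, min_cosine=-1.0)
    stops = hs.default_stopwords()
    for clist in candidates:
        lx = lexicons[clist.topic_name]
        for row in clist.rows:
            assert row.candidate not in lx.keywords
            assert row.candidate not in stops
            assert -1.0 <= row.cosine <= 1.0
            assert row.decision == "pending"


def test_absent_seeds_are_skipped_and_reported(model, lexicons):
    candidates = hs.propose_candidates(model, lexicons, top_k=5, min_cosine=0.0)
    flavors = next(c for c in candidates if c.topic_name == "Flavors")
    assert "mint" in flavors.skipped_seeds  # never occurs in the synonym corpus
    assert flavors.rows == []


def test_apply_review_monotone_and_idempotent(lexicons):
    row = Candidate(seed="want", candidate="crave2", cosine=0.9, decision="accept")
    dup = Candidate(seed="need", candidate="crave2", cosine=0.8, decision="accept")
    rejected = Candidate(seed="want", candidate="junk", cosine=0.7, decision="reject")
    reviewed = [CandidateList(topic_name="Appeal or Abuse Liability",
                              rows=[row, dup, rejected])]
    updated = hs.apply_review(lexicons, reviewed)
    appeal = updated["Appeal or Abuse Liability"]
    before = lexicons["Appeal or Abuse Liability"].keywords
    assert appeal.keywords == before | {"crave2"}
    assert appeal.provenance["crave2"] == EXPANDED
    assert all(appeal.provenance[kw] == SEED for kw in before)
    # original object untouched; all-reject review is the identity
    assert "crave2" not in before
    same = hs.apply_review(lexicons, [CandidateList("Flavors", rows=[
        Candidate(seed="mint", candidate="spearmint", cosine=0.9, decision="reject")])])
    assert same["Flavors"].keywords == lexicons["Flavors"].keywords


def test_apply_review_unknown_topic_errors(lexicons):
    with pytest.raises(KeyError, match="unknown topic"):
        hs.apply_review(lexicons, [CandidateList(topic_name="Nonexistent")])


def test_worksheet_roundtrip(tmp_path, model, lexicons):
    candidates = hs.propose_candidates(model, lexicons, top_k=10, min_cosine=0.0)
    path = hs.write_worksheet(candidates, tmp_path / "review.tsv")
    back = hs.read_worksheet(path)
    flat = lambda cls: [(c.topic_name, r.seed, r.candidate, round(r.cosine, 4), r.decision)
                        for c in cls for r in c.rows]
    assert flat(back) == flat(candidates)


def test_worksheet_rejects_bad_header(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("wrong\theader\n", "utf-8")
    with pytest.raises(ValueError, match="header"):
        hs.read_worksheet(bad)
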