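import pytest
from hypothesis import settings

import hookahscope as hs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicons():
    return hs.load_default_lexicons()


@pytest.fixture(scope="session")
def synth_1200():
    """A 1,200-tweet synthetic corpus with ground truth, shared across tests."""
    config = hs.GeneratorConfig(n_tweets=1200, seed=42)
    corpus, truth = hs.generate(config)
    return config, corpus, truth


@pytest.fixture(scope="session")
def clean_normalized(synth_1200, lexicons):
    """The filtered + normalized clean subset of the shared corpus."""
    _, corpus, _ = synth_1200
    clean, _report = hs.run_filter_chain(corpus)
    return hs.normalize_corpus(clean)


def make_record(tweet_id="t0", user_id="u0", text="hookah tonight", lang="en",
                is_retweet=False, bot_score=None):
    return hs.TweetRecord(tweet_id=tweet_id, user_id=user_id,
                          created_at="2017-06-01T12:00:00Z", text=text, lang=lang,
                          is_retweet=is_retweet, bot_score=bot_score)
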