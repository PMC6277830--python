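"""Synthetic tweet corpora with exact ground truth.

Platform terms forbid redistributing the original posts, so every pipeline
stage is exercised on generated corpora instead. The generator emulates the
study's raw stream: every post contains the tracked term ("hookah"), topics
are planted by injecting a keyword of the topic verbatim (in a randomized
surface form the normalization chain provably restores), filler comes from a
pseudo-word noise vocabulary kept disjoint from every lexicon keyword,
retweets duplicate an original text behind an "RT @user " prefix, non-English
posts carry a non-"en" language code, and bot accounts carry elevated bot
scores. Because keyword injection is the only source of topic signal,
end-to-end classification of the clean subset recovers the planted labels
exactly, not just statistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from hookahscope.classify import OverlapMatrix, PrevalenceReport, TopicAssignment, overlap_matrix, prevalence_report
from hookahscope.lexicon import LexiconSet, load_default_lexicons
from hookahscope.normalize import MENTION_TOKEN, NormalizationConfig, _normalize_text, default_stopwords, lemmatize
from hookahscope.records import Corpus, TweetRecord

# Planted per-topic rates default to the prevalence profile reported for the
# original 176,706-tweet analytic sample.
DEFAULT_TOPIC_RATES = {
    "Person Tagging": 0.2158,
    "Promotional or Social Events": 0.2020,
    "Appeal or Abuse Liability": 0.1812,
    "Hookah Use Behavior": 0.1167,
    "Polysubstance Use": 0.1095,
    "Buying or Selling": 0.0937,
    "Flavors": 0.0166,
    "Dislike of Hookah": 0.0059,
}

# Extra joint-draw probability for pairs observed to overlap more than
# independence predicts (buying-appeal overlap is the clearest case).
DEFAULT_COOCCURRENCE_BOOSTS = {
    ("Buying or Selling", "Appeal or Abuse Liability"): 0.025,
}

_NON_ENGLISH_FILLER = [
    "aqui", "bueno", "cachimba", "contigo", "fiesta", "fumar", "gracias",
    "humo", "muy", "noche", "sabor", "siempre",
]
_NON_ENGLISH_LANGS = ["es", "fr", "pt", "ar", "tr"]

_CONSONANTS = "bcdfgjklmnprstvz"
_SYLLABLE_VOWELS = "aeiou"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped corpus generation parameters.

    Rates mirror the original collection: roughly 64% of the raw stream was
    removed as retweets or non-English posts, and roughly half of what
    remained came from bot accounts. The defaults below plant retweets at
    55%, non-English originals at 10% of the remainder, and bot accounts at
    35% of users, which reproduces that attrition shape at any corpus size.
    """

    n_tweets: int = 1000
    seed: int = 0
    topic_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TOPIC_RATES))
    cooccurrence_boosts: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COOCCURRENCE_BOOSTS))
    retweet_rate: float = 0.55
    non_english_rate: float = 0.10
    bot_account_rate: float = 0.35
    n_users: Optional[int] = None
    noise_vocabulary_size: int = 200

    def __post_init__(self) -> None:
        if self.n_tweets < 0:
            raise ValueError("n_tweets must be >= 0")
        for name, p in {**self.topic_rates,
                        "retweet_rate": self.retweet_rate,
                        "non_english_rate": self.non_english_rate,
                        "bot_account_rate": self.bot_account_rate,
                        **{str(k): v for k, v in self.cooccurrence_boosts.items()}}.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {name} = {p} outside [0, 1]")
        unknown = set(self.topic_rates) - set(DEFAULT_TOPIC_RATES)
        if unknown:
            raise ValueError(f"unknown topics in topic_rates: {sorted(unknown)}")

    @property
    def effective_n_users(self) -> int:
        if self.n_users is not None:
            return max(1, self.n_users)
        return max(1, -(-self.n_tweets // 2))  # ~2 tweets per account


@dataclass(frozen=True)
class TweetTruth:
    topics: frozenset[str]
    is_bot_authored: bool
    is_retweet: bool
    is_english: bool

    @property
    def is_clean(self) -> bool:
        return self.is_english and not self.is_retweet and not self.is_bot_authored


@dataclass
class GroundTruth:
    """Per-tweet planted labels plus the derived clean subset."""

    per_tweet: dict[str, TweetTruth]
    topic_names: list[str]

    @property
    def clean_ids(self) -> list[str]:
        return [tid for tid, t in self.per_tweet.items() if t.is_clean]

    def planted_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in self.topic_names}
        for tid in self.clean_ids:
            for topic in self.per_tweet[tid].topics:
                counts[topic] += 1
        return counts


def _build_noise_vocab(rng: np.random.Generator, size: int, banned: set[str]) -> list[str]:
    """Pseudo-words whose lemmas collide with no keyword, stop word, or the
    tracked term."""
    vocab: list[str] = []
    seen: set[str] = set()
    stops = default_stopwords()
    while len(vocab) < size:
        n_syll = int(rng.integers(2, 4))
        word = "".join(
            _CONSONANTS[int(rng.integers(len(_CONSONANTS)))] +
            _SYLLABLE_VOWELS[int(rng.integers(len(_SYLLABLE_VOWELS)))]
            for _ in range(n_syll)
        )
        if word in seen or word in banned or word in stops:
            continue
        if lemmatize(word) in banned or lemmatize(word) in stops:
            continue
        seen.add(word)
        vocab.append(word)
    return vocab


def _surface_variants(keyword: str, config: NormalizationConfig) -> list[str]:
    """Surface forms of a keyword that the normalization chain restores to it."""
    target = keyword.split()
    raw = [keyword, keyword.capitalize(), keyword.upper(), keyword + "!",
           keyword.capitalize() + ",", keyword + "."]
    ok = [s for s in raw if list(_normalize_text(s, config)[0]) == target]
    if not ok:
        raise RuntimeError(f"no surface form of {keyword!r} survives normalization")
    return ok


def _random_handle(rng: np.random.Generator) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    n = int(rng.integers(4, 9))
    return "".join(letters[int(rng.integers(26))] for _ in range(n)) + str(int(rng.integers(100)))


def generate(config: GeneratorConfig = GeneratorConfig(),
             lexicons: LexiconSet | None = None) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus plus exact ground truth, reproducible from the seed."""
    lexicons = lexicons or load_default_lexicons()
    topic_names = lexicons.topic_names
    # exact recovery relies on keywords belonging to exactly one topic
    for i, la in enumerate(lexicons):
        for lb in list(lexicons)[i + 1:]:
            shared = la.keywords & lb.keywords
            if shared:
                raise ValueError(f"keyword(s) {sorted(shared)} shared between topics")

    rng = np.random.default_rng(config.seed)
    norm_config = NormalizationConfig()
    banned = {w for kw in lexicons.all_keywords() for w in kw.split()} | {"hookah"}
    noise = _build_noise_vocab(rng, config.noise_vocabulary_size, banned)
    variants = {
        kw: (None if kw == MENTION_TOKEN else _surface_variants(kw, norm_config))
        for kw in lexicons.all_keywords()
    }

    n_users = config.effective_n_users
    user_is_bot = rng.random(n_users) < config.bot_account_rate
    user_ids = [f"user{u:05d}" for u in range(n_users)]

    rate_items = [(t, config.topic_rates.get(t, 0.0)) for t in topic_names]
    boost_items = sorted(config.cooccurrence_boosts.items())

    records: list[TweetRecord] = []
    truths: dict[str, TweetTruth] = {}
    originals: list[TweetRecord] = []

    for i in range(config.n_tweets):
        tweet_id = f"t{i:07d}"
        uidx = int(rng.integers(n_users))
        user_id = user_ids[uidx]
        is_bot = bool(user_is_bot[uidx])
        bot_score = float(0.90 + 0.1 * rng.random()) if is_bot else float(0.1 * rng.random())
        created_at = f"2017-04-01T{(i * 7) % 24:02d}:{(i * 13) % 60:02d}:{i % 60:02d}Z"

        make_retweet = originals and rng.random() < config.retweet_rate
        if make_retweet:
            src = originals[int(rng.integers(len(originals)))]
            text = f"RT @{_random_handle(rng)} {src.text}"
            rec = TweetRecord(tweet_id=tweet_id, user_id=user_id, created_at=created_at,
                              text=text, lang=src.lang, is_retweet=bool(rng.random() < 0.5),
                              bot_score=bot_score)
            truths[tweet_id] = TweetTruth(topics=frozenset(), is_bot_authored=is_bot,
                                          is_retweet=True, is_english=src.lang == "en")
            records.append(rec)
            continue

        non_english = rng.random() < config.non_english_rate
        if non_english:
            k = int(rng.integers(3, 8))
            units = [_NON_ENGLISH_FILLER[int(rng.integers(len(_NON_ENGLISH_FILLER)))]
                     for _ in range(k)]
            units.insert(int(rng.integers(len(units) + 1)), "hookah")
            lang = _NON_ENGLISH_LANGS[int(rng.integers(len(_NON_ENGLISH_LANGS)))]
            rec = TweetRecord(tweet_id=tweet_id, user_id=user_id, created_at=created_at,
                              text=" ".join(units), lang=lang, is_retweet=False,
                              bot_score=bot_score)
            truths[tweet_id] = TweetTruth(topics=frozenset(), is_bot_authored=is_bot,
                                          is_retweet=False, is_english=False)
            records.append(rec)
            originals.append(rec)
            continue

        # English original: plant topics
        draws = rng.random(len(rate_items))
        topics = {t for (t, p), d in zip(rate_items, draws) if d < p}
        for (ta, tb), boost in boost_items:
            if rng.random() < boost:
                topics |= {ta, tb}

        k = int(rng.integers(4, 9))
        units = [noise[int(rng.integers(len(noise)))] for _ in range(k)]
        hookah_surface = ["hookah", "Hookah", "#hookah", "hookah!"][int(rng.integers(4))]
        units.insert(int(rng.integers(len(units) + 1)), hookah_surface)
        for topic in sorted(topics):
            lx = lexicons[topic]
            kws = sorted(lx.keywords)
            kw = kws[int(rng.integers(len(kws)))]
            if kw == MENTION_TOKEN:
                surface = f"@{_random_handle(rng)}"
            else:
                opts = variants[kw]
                surface = opts[int(rng.integers(len(opts)))]
            units.insert(int(rng.integers(len(units) + 1)), surface)

        rec = TweetRecord(tweet_id=tweet_id, user_id=user_id, created_at=created_at,
                          text=" ".join(units), lang="en", is_retweet=False,
                          bot_score=bot_score)
        truths[tweet_id] = TweetTruth(topics=frozenset(topics), is_bot_authored=is_bot,
                                      is_retweet=False, is_english=True)
        records.append(rec)
        originals.append(rec)

    corpus = Corpus.__new__(Corpus)
    corpus.records = records
    corpus.provenance = f"synthetic corpus (seed={config.seed}, n={config.n_tweets})"
    return corpus, GroundTruth(per_tweet=truths, topic_names=list(topic_names))


def expected_report(truth: GroundTruth) -> tuple[PrevalenceReport, OverlapMatrix]:
    """Exact counting over planted labels of the clean subset, with the same
    rounding rules the classifier's reports use."""
    clean = truth.clean_ids
    assignments = [
        TopicAssignment(tweet_id=tid, topics=truth.per_tweet[tid].topics)
        for tid in clean
    ]
    report = prevalence_report(assignments, corpus_size=len(clean),
                               topic_names=truth.topic_names)
    matrix = overlap_matrix(assignments, topic_names=truth.topic_names)
    return report, matrix
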