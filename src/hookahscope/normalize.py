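"""The six-step text normalization chain.

Order is fixed: (1) user-mention canonicalization, (2) lowercasing,
(3) non-printable/emoji removal, (4) punctuation removal under the apostrophe
and hashtag policies, (5) stop-word removal, (6) lemmatization. Mentions are
canonicalized first so punctuation stripping cannot destroy the "@" marker the
person-tagging topic depends on. The stop list is re-applied after
lemmatization so no output token is ever a stop word.

The lemmatizer is a deterministic dictionary-plus-suffix-rule engine covering
regular English plurals and -ed/-ing inflections plus a short irregular table.
It satisfies the "cats"/"cat's" → "cat" contract; golden tests pin its
behavior so results are reproducible independent of any NLP library version.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

from hookahscope.records import Corpus, TweetRecord

MENTION_TOKEN = "@username"
_MENTION_RE = re.compile(r"@\w+\W*", re.UNICODE)

_VOWELS = set("aeiou")

# Inflected form -> lemma, for forms the suffix rules cannot reach.
_IRREGULAR = {
    "bought": "buy",
    "sold": "sell",
    "paid": "pay",
    "used": "use",
    "went": "go",
    "got": "get",
    "gotten": "get",
    "drank": "drink",
    "drunk": "drink",
    "men": "man",
    "women": "woman",
    "children": "child",
    "feet": "foot",
    "teeth": "tooth",
    "mice": "mouse",
    "lives": "life",
    "leaves": "leaf",
}

# Words ending in -ing that are not progressive verb forms.
_ING_NOUNS = {
    "anything",
    "bring",
    "cling",
    "evening",
    "everything",
    "fling",
    "king",
    "morning",
    "nothing",
    "ring",
    "sing",
    "something",
    "spring",
    "sting",
    "string",
    "swing",
    "thing",
    "wing",
}


def _is_cvc(stem: str) -> bool:
    """Consonant-vowel-consonant ending (Porter-style, excluding w/x/y)."""
    if len(stem) < 3:
        return False
    a, b, c = stem[-3], stem[-2], stem[-1]
    return c not in _VOWELS and c not in "wxy" and b in _VOWELS and a not in _VOWELS


def lemmatize(token: str) -> str:
    """Map one lowercase token to its dictionary base form.

    Tokens containing non-alphabetic characters (mentions, numbers, hashtags
    kept verbatim) pass through unchanged.
    """
    if not token.isalpha():
        return token
    if token in _IRREGULAR:
        return _IRREGULAR[token]
    n = len(token)
    if n <= 3:
        return token
    # progressive: -ing
    if token.endswith("ing") and n > 4 and token not in _ING_NOUNS:
        stem = token[:-3]
        if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in "lsz":
            return stem[:-1]  # running -> run
        if _is_cvc(stem):
            return stem + "e"  # craving -> crave, smoking -> smoke
        return stem  # paying -> pay
    # past tense: -ed (but -eed words like "need", "weed" are base forms)
    if token.endswith("ed") and not token.endswith("eed") and n >= 5:
        stem = token[:-2]
        if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in "lsz":
            return stem[:-1]  # stopped -> stop
        if len(stem) <= 4 and _is_cvc(stem):
            return stem + "e"  # hated -> hate, craved -> crave
        return stem  # wanted -> want, ordered -> order
    # plurals
    if token.endswith("ies") and n >= 5:
        return token[:-3] + "y"  # parties -> party
    if token.endswith(("sses", "xes", "ches", "shes", "zes", "oes")):
        return token[:-2]  # glasses -> glass, boxes -> box
    if token.endswith("s") and not token.endswith(("ss", "us", "is", "es")):
        return token[:-1]  # cats -> cat, cocktails -> cocktail
    return token


@lru_cache(maxsize=1)
def default_stopwords() -> frozenset[str]:
    """The packaged English stop-word list (one word per line, UTF-8).

    Negation contractions ("dont", "cant") are deliberately absent so phrases
    like "dont hookah" survive as matchable bigrams.
    """
    text = resources.files("hookahscope.data").joinpath("stopwords.txt").read_text("utf-8")
    words = frozenset(w.strip() for w in text.splitlines() if w.strip())
    if not words or "a" not in words or "the" not in words:
        raise RuntimeError("packaged stop-word list is corrupted")
    return words


@dataclass(frozen=True)
class NormalizationConfig:
    """Knobs of the normalization chain.

    stop_words : active stop list (surface forms, lowercase).
    keep_mention_token : keep the canonical "@username" token (required by the
        person-tagging topic) or drop mentions entirely.
    hashtag_policy : "strip_symbol" ("#hookah" -> "hookah") or "keep".
    apostrophe_policy : "delete" ("don't" -> "dont") or "split" ("don't" ->
        "don", "t").
    """

    stop_words: frozenset[str] = field(default_factory=default_stopwords)
    keep_mention_token: bool = True
    hashtag_policy: str = "strip_symbol"
    apostrophe_policy: str = "delete"

    def __post_init__(self) -> None:
        if self.hashtag_policy not in ("strip_symbol", "keep"):
            raise ValueError(f"unknown hashtag_policy {self.hashtag_policy!r}")
        if self.apostrophe_policy not in ("delete", "split"):
            raise ValueError(f"unknown apostrophe_policy {self.apostrophe_policy!r}")
        if not self.stop_words:
            raise ValueError("stop_words must be non-empty")


@dataclass(frozen=True)
class NormalizedTweet:
    """Token sequence after the six-step chain, linked to its source record."""

    tweet_id: str
    tokens: tuple[str, ...]
    mention_count: int = 0


_APOSTROPHES = "'’ʼ"
_PRINTABLE_DROP_CATEGORIES = ("So", "Sk", "Sm", "Cc", "Cf", "Cs", "Co", "Cn")


def _strip_unprintable(token: str) -> str:
    return "".join(
        ch
        for ch in token
        if unicodedata.category(ch) not in _PRINTABLE_DROP_CATEGORIES and ch.isprintable()
    )


def _strip_punctuation(token: str, keep_hash: bool) -> str:
    out = []
    for i, ch in enumerate(token):
        if ch.isalnum():
            out.append(ch)
        elif ch == "#" and keep_hash and i == 0:
            out.append(ch)
    return "".join(out)


def normalize(record: TweetRecord, config: NormalizationConfig = NormalizationConfig()) -> NormalizedTweet:
    """Apply the six-step chain to one record; degenerate texts yield ()."""
    tokens, mentions = _normalize_text(record.text, config)
    return NormalizedTweet(tweet_id=record.tweet_id, tokens=tokens, mention_count=mentions)


def _normalize_text(text: str, config: NormalizationConfig) -> tuple[tuple[str, ...], int]:
    mention_count = 0
    out: list[str] = []
    for raw in text.split():
        # (1) mention canonicalization
        if _MENTION_RE.fullmatch(raw):
            mention_count += 1
            if config.keep_mention_token:
                out.append(MENTION_TOKEN)
            continue
        # (2) lowercase
        tok = raw.lower()
        # (3) non-printable / emoji removal
        tok = _strip_unprintable(tok)
        # (4) punctuation removal under apostrophe/hashtag policies
        if config.apostrophe_policy == "delete":
            parts = [tok.translate({ord(a): None for a in _APOSTROPHES})]
        else:
            parts = re.split(f"[{_APOSTROPHES}]", tok)
        keep_hash = config.hashtag_policy == "keep"
        for part in parts:
            part = _strip_punctuation(part, keep_hash=keep_hash)
            if not part:
                continue
            # (5) stop-word removal
            if part in config.stop_words:
                continue
            # (6) lemmatization (stop list re-applied on the lemma)
            lemma = part if part == MENTION_TOKEN else lemmatize(part)
            if lemma and lemma not in config.stop_words:
                out.append(lemma)
    return tuple(out), mention_count


def normalize_corpus(corpus: Corpus | Iterable[TweetRecord],
                     config: NormalizationConfig = NormalizationConfig()) -> list[NormalizedTweet]:
    """One NormalizedTweet per record, input order preserved, deterministic."""
    return [normalize(rec, config) for rec in corpus]


def normalize_keyword(keyword: str, config: NormalizationConfig = NormalizationConfig()) -> str:
    """Normalize a lexicon n-gram with the same chain used on tweets."""
    tokens, _ = _normalize_text(keyword, config)
    return " ".join(tokens)
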