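"""Topic lexicons: the packaged eight-topic default set and its file format.

A lexicon file is structured text: a ``[topic: Name]`` header line followed by
one n-gram per line. Blank lines and ``#`` comments are ignored on read; the
writer emits the canonical form (headers in set order, keywords sorted), so
write -> read -> write is byte-stable.

Keywords are stored in normalized form — lowercase, lemmatized, apostrophes
deleted — because classification matches them against the normalized lemma
sequence of each tweet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from hookahscope.normalize import MENTION_TOKEN, default_stopwords

SEED = "seed"
EXPANDED = "expanded-accepted"

DEFAULT_TOPIC_ORDER = (
    "Person Tagging",
    "Promotional or Social Events",
    "Appeal or Abuse Liability",
    "Hookah Use Behavior",
    "Polysubstance Use",
    "Buying or Selling",
    "Flavors",
    "Dislike of Hookah",
)


@dataclass
class TopicLexicon:
    """A named topic with its unigram/bigram keyword set.

    provenance maps each keyword to "seed" (original list) or
    "expanded-accepted" (added through embedding-assisted review).
    """

    topic_name: str
    keywords: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"lexicon {self.topic_name!r} has no keywords")
        stops = default_stopwords()
        for kw in self.keywords:
            if kw != kw.lower():
                raise ValueError(f"{self.topic_name}: keyword {kw!r} is not lowercase")
            if kw in stops:
                raise ValueError(f"{self.topic_name}: keyword {kw!r} is a stop word")
            if not (1 <= len(kw.split()) <= 2):
                raise ValueError(f"{self.topic_name}: keyword {kw!r} is not a unigram/bigram")
        for kw in self.keywords:
            self.provenance.setdefault(kw, SEED)

    @property
    def unigrams(self) -> set[str]:
        return {kw for kw in self.keywords if " " not in kw}

    @property
    def bigrams(self) -> set[str]:
        return {kw for kw in self.keywords if " " in kw}


@dataclass
class LexiconSet:
    """Ordered collection of topic lexicons with unique names."""

    lexicons: list[TopicLexicon]
    version: str = "default-v1"

    def __post_init__(self) -> None:
        names = [lx.topic_name for lx in self.lexicons]
        if len(names) != len(set(names)):
            raise ValueError("duplicate topic names in lexicon set")

    def __iter__(self):
        return iter(self.lexicons)

    def __len__(self) -> int:
        return len(self.lexicons)

    @property
    def topic_names(self) -> list[str]:
        return [lx.topic_name for lx in self.lexicons]

    def __getitem__(self, topic_name: str) -> TopicLexicon:
        for lx in self.lexicons:
            if lx.topic_name == topic_name:
                return lx
        raise KeyError(topic_name)

    def all_keywords(self) -> set[str]:
        out: set[str] = set()
        for lx in self.lexicons:
            out |= lx.keywords
        return out


def _parse_lexicon_text(text: str, version: str) -> LexiconSet:
    lexicons: list[TopicLexicon] = []
    current_name: str | None = None
    current_words: list[str] = []

    def flush() -> None:
        nonlocal current_name, current_words
        if current_name is not None:
            lexicons.append(TopicLexicon(topic_name=current_name, keywords=set(current_words)))
        current_name, current_words = None, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[topic:") and line.endswith("]"):
            flush()
            current_name = line[len("[topic:"):-1].strip()
            if not current_name:
                raise ValueError(f"line {lineno}: empty topic name")
        elif current_name is None:
            raise ValueError(f"line {lineno}: keyword before any [topic: ...] header")
        else:
            current_words.append(line)
    flush()
    if not lexicons:
        raise ValueError("no topics found in lexicon file")
    return LexiconSet(lexicons=lexicons, version=version)


def read_lexicons(path: str | Path, version: str | None = None) -> LexiconSet:
    path = Path(path)
    return _parse_lexicon_text(path.read_text("utf-8"), version or path.stem)


def write_lexicons(lexicons: LexiconSet, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for lx in lexicons:
            fh.write(f"[topic: {lx.topic_name}]\n")
            for kw in sorted(lx.keywords):
                fh.write(f"{kw}\n")
    return path


def load_default_lexicons() -> LexiconSet:
    """The packaged eight-topic default set.

    Seven topics carry the published common-word lists; the eighth (Dislike of
    Hookah) carries the dislike exemplars ("hate", "quit", "dislike") plus the
    negated bigrams "dont hookah" and "quit hookah" (apostrophe-deleted form).
    The person-tagging topic's sole keyword is the canonical mention token.
    """
    text = resources.files("hookahscope.data").joinpath("default_lexicons.txt").read_text("utf-8")
    lexicons = _parse_lexicon_text(text, version="default-v1")
    if tuple(lexicons.topic_names) != DEFAULT_TOPIC_ORDER:
        raise RuntimeError("packaged default lexicons are corrupted")
    if lexicons["Person Tagging"].keywords != {MENTION_TOKEN}:
        raise RuntimeError("packaged default lexicons are corrupted")
    return lexicons
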