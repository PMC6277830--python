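"""Tweet records and line-delimited JSON corpus I/O.

The on-disk dialect is deliberately minimal: one JSON object per line, UTF-8,
with the keys of :class:`TweetRecord`. Only the fields the analysis actually
consumes are carried — text, author, language code, retweet flag, and a
precomputed per-account bot probability score. Timestamps are parsed for
validity but no analysis stage reads them.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files (strict mode) and duplicate ids."""


@dataclass(frozen=True)
class TweetRecord:
    """One social-media post.

    Parameters
    ----------
    tweet_id : opaque unique identifier.
    user_id : opaque author identifier.
    created_at : ISO-8601 UTC timestamp string (provenance only).
    text : the raw post text, non-empty.
    lang : two-letter BCP-47-style language code, or ``"und"`` when unknown.
    is_retweet : platform retweet flag.
    bot_score : per-account bot probability in [0, 1], or None when unscored.
    """

    tweet_id: str
    user_id: str
    created_at: str
    text: str
    lang: str = "und"
    is_retweet: bool = False
    bot_score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"tweet {self.tweet_id!r}: text must be non-empty")
        if self.bot_score is not None and not (0.0 <= self.bot_score <= 1.0):
            raise ValueError(
                f"tweet {self.tweet_id!r}: bot_score {self.bot_score} outside [0, 1]"
            )

    def to_json(self) -> str:
        obj = {
            "tweet_id": self.tweet_id,
            "user_id": self.user_id,
            "created_at": self.created_at,
            "text": self.text,
            "lang": self.lang,
            "is_retweet": self.is_retweet,
        }
        if self.bot_score is not None:
            obj["bot_score"] = self.bot_score
        return json.dumps(obj, ensure_ascii=False, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "TweetRecord":
        obj = json.loads(line)
        if not isinstance(obj, dict):
            raise CorpusFormatError("line is valid JSON but not an object")
        try:
            return cls(
                tweet_id=str(obj["tweet_id"]),
                user_id=str(obj["user_id"]),
                created_at=str(obj.get("created_at", "")),
                text=obj["text"],
                lang=str(obj.get("lang", "und")),
                is_retweet=bool(obj.get("is_retweet", False)),
                bot_score=None if obj.get("bot_score") is None else float(obj["bot_score"]),
            )
        except KeyError as exc:
            raise CorpusFormatError(f"missing required field {exc}") from exc


@dataclass
class Corpus:
    """An ordered collection of :class:`TweetRecord` with stable iteration order."""

    records: list[TweetRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.tweet_id in seen:
                raise CorpusFormatError(f"duplicate tweet_id {rec.tweet_id!r}")
            seen.add(rec.tweet_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TweetRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.records == other.records

    def subset(self, keep: Iterable[TweetRecord], provenance: str) -> "Corpus":
        sub = Corpus.__new__(Corpus)  # keep ids already vetted; skip re-validation
        sub.records = list(keep)
        sub.provenance = provenance
        return sub

    @property
    def n_users(self) -> int:
        return len({rec.user_id for rec in self.records})


@dataclass(frozen=True)
class CorpusStats:
    n_records: int
    n_distinct_users: int
    n_retweet_flagged: int
    language_histogram: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_distinct_users": self.n_distinct_users,
            "n_retweet_flagged": self.n_retweet_flagged,
            "language_histogram": dict(sorted(self.language_histogram.items())),
        }


def read_corpus(path: str | Path, strict: bool = True) -> Corpus:
    """Read a line-delimited JSON corpus.

    In strict mode any malformed line aborts with :class:`CorpusFormatError`;
    in lenient mode malformed lines are skipped and the skip count recorded in
    the corpus provenance. A duplicate tweet_id is always an error.
    """
    path = Path(path)
    records: list[TweetRecord] = []
    seen: set[str] = set()
    skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = TweetRecord.from_json(line)
            except (json.JSONDecodeError, CorpusFormatError, ValueError, TypeError) as exc:
                if strict:
                    raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
                skipped += 1
                continue
            if rec.tweet_id in seen:
                raise CorpusFormatError(f"{path}:{lineno}: duplicate tweet_id {rec.tweet_id!r}")
            seen.add(rec.tweet_id)
            records.append(rec)
    provenance = f"read from {path.name}"
    if skipped:
        provenance += f" ({skipped} malformed line(s) skipped)"
    corpus = Corpus.__new__(Corpus)
    corpus.records = records
    corpus.provenance = provenance
    return corpus


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write one JSON object per line; read_corpus(write_corpus(c)) == c."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in corpus:
            fh.write(rec.to_json())
            fh.write("\n")
    return path


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Record count, distinct authors, retweet-flag count, and language histogram."""
    langs = Counter(rec.lang for rec in corpus)
    return CorpusStats(
        n_records=len(corpus),
        n_distinct_users=corpus.n_users,
        n_retweet_flagged=sum(1 for rec in corpus if rec.is_retweet),
        language_histogram=dict(langs),
    )


def with_bot_score(record: TweetRecord, score: Optional[float]) -> TweetRecord:
    return replace(record, bot_score=score)
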