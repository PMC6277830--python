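"""Unigram/bigram frequency tables over normalized tweets.

Bigrams are contiguous token pairs within one tweet and never span tweets.
Counts feed the topic-discovery stage: a word-cloud renderer (or any reader)
consumes the exported TSV directly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from hookahscope.normalize import NormalizedTweet


@dataclass
class NgramTable:
    """Occurrence counts for n-grams of a fixed order n (1 or 2)."""

    n: int
    entries: dict[str, int] = field(default_factory=dict)
    total_tokens: int = 0

    def __post_init__(self) -> None:
        if self.n not in (1, 2):
            raise ValueError(f"n must be 1 or 2, got {self.n}")

    def __len__(self) -> int:
        return len(self.entries)


def count_ngrams(tweets: Iterable[NormalizedTweet], n: int) -> NgramTable:
    """Count n-grams (n=1 unigrams, n=2 contiguous bigrams) over the tweets."""
    if n not in (1, 2):
        raise ValueError(f"n must be 1 or 2, got {n}")
    counts: Counter[str] = Counter()
    total = 0
    for tweet in tweets:
        toks = tweet.tokens
        total += len(toks)
        if n == 1:
            counts.update(toks)
        else:
            counts.update(" ".join(pair) for pair in zip(toks, toks[1:]))
    return NgramTable(n=n, entries=dict(counts), total_tokens=total)


def top_k(table: NgramTable, k: int) -> list[tuple[str, int]]:
    """k most frequent n-grams, descending by count, ties lexicographic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table.entries.items(), key=lambda item: (-item[1], item[0]))
    return ranked[:k]


def export_wordcloud_data(table: NgramTable, path: str | Path) -> Path:
    """Write the full table as TSV (header "ngram\\tcount"), descending order."""
    path = Path(path)
    rows = top_k(table, max(1, len(table))) if len(table) else []
    with path.open("w", encoding="utf-8") as fh:
        fh.write("ngram\tcount\n")
        for ngram, count in rows:
            fh.write(f"{ngram}\t{count}\n")
    return path


def read_wordcloud_data(path: str | Path, n: int) -> NgramTable:
    """Re-parse an exported TSV (round-trip counterpart of export)."""
    entries: dict[str, int] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if header.rstrip("\n") != "ngram\tcount":
            raise ValueError(f"unexpected header {header!r}")
        for line in fh:
            ngram, count = line.rstrip("\n").split("\t")
            entries[ngram] = int(count)
    total = sum(entries.values()) if n == 1 else 0
    return NgramTable(n=n, entries=entries, total_tokens=total)
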