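"""Rule-based multi-label topic classification and prevalence/overlap reporting.

A tweet belongs to a topic iff at least one of that topic's keywords is
present in the tweet's normalized lemma sequence — unigrams as whole tokens,
bigrams as contiguous token pairs, never substrings (so "hit" cannot match
inside "white"). Person tagging fires on the canonical "@username" token.
Classification is multi-label by construction; prevalence is denominated by
the full analytic corpus, and topic co-occurrence is reported as a symmetric
matrix whose diagonal holds the per-topic counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from hookahscope.lexicon import LexiconSet
from hookahscope.normalize import NormalizedTweet


def round_percent(count: int, denominator: int) -> float:
    """100 * count / denominator, rounded half-up to two decimals.

    Half-up (not banker's) rounding, applied uniformly across the package.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = (Decimal(count) * 100) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class TopicAssignment:
    """The (possibly empty) set of topic labels attached to one tweet."""

    tweet_id: str
    topics: frozenset[str] = frozenset()
    matched_keywords: dict[str, list[str]] = field(default_factory=dict)


def classify_tweet(tweet: NormalizedTweet, lexicons: LexiconSet) -> TopicAssignment:
    """Assign every topic with >=1 keyword present in the token sequence."""
    tokens = tweet.tokens
    token_set = set(tokens)
    bigram_set = {f"{a} {b}" for a, b in zip(tokens, tokens[1:])}
    topics: list[str] = []
    matched: dict[str, list[str]] = {}
    for lx in lexicons:
        hits = sorted((lx.unigrams & token_set) | (lx.bigrams & bigram_set))
        if hits:
            topics.append(lx.topic_name)
            matched[lx.topic_name] = hits
    return TopicAssignment(tweet_id=tweet.tweet_id, topics=frozenset(topics),
                           matched_keywords=matched)


def classify_corpus(tweets: Iterable[NormalizedTweet], lexicons: LexiconSet) -> list[TopicAssignment]:
    """One assignment per tweet; each tweet is classified independently."""
    return [classify_tweet(tw, lexicons) for tw in tweets]


@dataclass
class PrevalenceReport:
    """Per-topic counts/percentages plus coverage over the analytic corpus.

    Coverage is the share of tweets carrying at least one topic label;
    percentages are 100 * count / corpus_size rounded half-up to 2 decimals.
    Topics are ordered by descending prevalence, ties lexicographic.
    """

    corpus_size: int
    topic_counts: dict[str, int]
    coverage_count: int

    def __post_init__(self) -> None:
        if self.corpus_size <= 0:
            raise ValueError("corpus_size must be positive")
        if not (0 <= self.coverage_count <= self.corpus_size):
            raise ValueError("coverage count outside [0, corpus_size]")

    @property
    def uncovered_count(self) -> int:
        return self.corpus_size - self.coverage_count

    @property
    def coverage_percent(self) -> float:
        return round_percent(self.coverage_count, self.corpus_size)

    @property
    def uncovered_percent(self) -> float:
        return round_percent(self.uncovered_count, self.corpus_size)

    def topic_percent(self, topic: str) -> float:
        return round_percent(self.topic_counts[topic], self.corpus_size)

    def ranked_topics(self) -> list[tuple[str, int, float]]:
        """(topic, count, percent), descending count, ties lexicographic."""
        order = sorted(self.topic_counts.items(), key=lambda item: (-item[1], item[0]))
        return [(t, c, round_percent(c, self.corpus_size)) for t, c in order]

    def to_dict(self) -> dict:
        return {
            "corpus_size": self.corpus_size,
            "topics": [
                {"topic": t, "count": c, "percent": p} for t, c, p in self.ranked_topics()
            ],
            "coverage": {"count": self.coverage_count, "percent": self.coverage_percent},
            "uncovered": {"count": self.uncovered_count, "percent": self.uncovered_percent},
        }


class OverlapMatrix:
    """Symmetric topic co-occurrence matrix (a pandas DataFrame underneath).

    Cell (i, j) counts tweets labeled with both topic i and topic j; the
    diagonal holds per-topic totals.
    """

    def __init__(self, frame: pd.DataFrame):
        if not frame.index.equals(frame.columns):
            raise ValueError("overlap matrix must be square with matching labels")
        values = frame.to_numpy()
        if (values < 0).any() or (values != values.T).any():
            raise ValueError("overlap matrix must be symmetric and non-negative")
        self.frame = frame

    @property
    def topics(self) -> list[str]:
        return list(self.frame.index)

    def count(self, topic_a: str, topic_b: str) -> int:
        return int(self.frame.loc[topic_a, topic_b])

    def overlap_percent(self, topic_a: str, topic_b: str, corpus_size: int) -> float:
        return round_percent(self.count(topic_a, topic_b), corpus_size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OverlapMatrix):
            return NotImplemented
        return self.frame.equals(other.frame)


def prevalence_report(assignments: Sequence[TopicAssignment], corpus_size: int,
                      topic_names: Sequence[str] | None = None) -> PrevalenceReport:
    """Count labels over the assignments, denominated by ``corpus_size``."""
    if corpus_size < len(assignments):
        raise ValueError("corpus_size smaller than the number of assignments")
    names = list(topic_names) if topic_names is not None else sorted(
        {t for a in assignments for t in a.topics}
    )
    counts = {name: 0 for name in names}
    covered = 0
    for a in assignments:
        if a.topics:
            covered += 1
        for t in a.topics:
            counts[t] = counts.get(t, 0) + 1
    return PrevalenceReport(corpus_size=corpus_size, topic_counts=counts,
                            coverage_count=covered)


def overlap_matrix(assignments: Sequence[TopicAssignment],
                   topic_names: Sequence[str] | None = None) -> OverlapMatrix:
    """Pairwise co-label counts; diagonal equals per-topic totals."""
    names = list(topic_names) if topic_names is not None else sorted(
        {t for a in assignments for t in a.topics}
    )
    frame = pd.DataFrame(0, index=names, columns=names, dtype=int)
    idx = {name: i for i, name in enumerate(names)}
    values = frame.to_numpy()
    for a in assignments:
        labeled = sorted(t for t in a.topics if t in idx)
        for i, ta in enumerate(labeled):
            values[idx[ta], idx[ta]] += 1
            for tb in labeled[i + 1:]:
                values[idx[ta], idx[tb]] += 1
                values[idx[tb], idx[ta]] += 1
    return OverlapMatrix(pd.DataFrame(values, index=names, columns=names))


def write_assignments(assignments: Iterable[TopicAssignment], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for a in assignments:
            fh.write(json.dumps({
                "tweet_id": a.tweet_id,
                "topics": sorted(a.topics),
                "matched_keywords": {t: a.matched_keywords[t] for t in sorted(a.matched_keywords)},
            }, ensure_ascii=False))
            fh.write("\n")
    return path


def report_to_files(report: PrevalenceReport, matrix: OverlapMatrix,
                    prefix: str | Path) -> list[Path]:
    """Write prevalence + overlap as TSV and JSON mirrors under a path prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    prevalence_tsv = prefix.with_name(prefix.name + "_prevalence.tsv")
    with prevalence_tsv.open("w", encoding="utf-8") as fh:
        fh.write("topic\tcount\tpercent\n")
        for topic, count, pct in report.ranked_topics():
            fh.write(f"{topic}\t{count}\t{pct:.2f}\n")
        fh.write(f"[coverage]\t{report.coverage_count}\t{report.coverage_percent:.2f}\n")
        fh.write(f"[uncovered]\t{report.uncovered_count}\t{report.uncovered_percent:.2f}\n")
    paths.append(prevalence_tsv)

    matrix_tsv = prefix.with_name(prefix.name + "_overlap.tsv")
    matrix.frame.to_csv(matrix_tsv, sep="\t", index_label="topic")
    paths.append(matrix_tsv)

    prevalence_json = prefix.with_name(prefix.name + "_prevalence.json")
    prevalence_json.write_text(json.dumps(report.to_dict(), indent=2) + "\n", "utf-8")
    paths.append(prevalence_json)

    matrix_json = prefix.with_name(prefix.name + "_overlap.json")
    matrix_json.write_text(json.dumps({
        "topics": matrix.topics,
        "counts": matrix.frame.to_numpy().tolist(),
    }, indent=2) + "\n", "utf-8")
    paths.append(matrix_json)
    return paths


def read_overlap_tsv(path: str | Path) -> OverlapMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="topic")
    frame.columns.name = None
    frame.index.name = None
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return OverlapMatrix(frame.astype(int))
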