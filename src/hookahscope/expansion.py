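"""Embedding-assisted lexicon expansion with a mandatory human-review round-trip.

For each seed unigram of each topic that made it into the embedding
vocabulary, the nearest cosine neighbors are proposed as candidate keywords.
Nothing is ever auto-accepted: candidates go out as a TSV worksheet
(topic, seed, candidate, cosine, decision), a reviewer edits the decision
column, and ``apply_review`` folds the accepted rows back into the lexicons
with provenance "expanded-accepted". Seed keywords are never removed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from hookahscope.embedding import EmbeddingModel
from hookahscope.lexicon import EXPANDED, LexiconSet
from hookahscope.normalize import MENTION_TOKEN, default_stopwords

DECISIONS = ("pending", "accept", "reject")
WORKSHEET_HEADER = "topic\tseed\tcandidate\tcosine\tdecision"


@dataclass
class Candidate:
    seed: str
    candidate: str
    cosine: float
    decision: str = "pending"

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.cosine <= 1.0 + 1e-9):
            raise ValueError(f"cosine {self.cosine} outside [-1, 1]")
        if self.decision not in DECISIONS:
            raise ValueError(f"unknown decision {self.decision!r}")


@dataclass
class CandidateList:
    """Proposed expansion terms for one topic, plus seeds that were skipped
    because they never reached the embedding vocabulary."""

    topic_name: str
    rows: list[Candidate] = field(default_factory=list)
    skipped_seeds: list[str] = field(default_factory=list)


def propose_candidates(model: EmbeddingModel, lexicons: LexiconSet,
                       top_k: int = 20, min_cosine: float = 0.5) -> list[CandidateList]:
    """Nearest-neighbor candidates per topic seed unigram.

    Per seed: up to ``top_k`` neighbors with cosine >= ``min_cosine``,
    excluding stop words, the canonical mention token, and anything already in
    that topic's lexicon. Seeds absent from the vocabulary are recorded in
    ``skipped_seeds``. All decisions start "pending".
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    stops = default_stopwords()
    out: list[CandidateList] = []
    for lx in lexicons:
        clist = CandidateList(topic_name=lx.topic_name)
        for seed in sorted(lx.unigrams):
            if seed == MENTION_TOKEN or seed not in model:
                if seed != MENTION_TOKEN:
                    clist.skipped_seeds.append(seed)
                continue
            neighbors = model.most_similar(seed, top_k=top_k + len(lx.keywords),
                                           exclude=lx.keywords | stops | {MENTION_TOKEN})
            kept = [(tok, sim) for tok, sim in neighbors if sim >= min_cosine][:top_k]
            clist.rows.extend(Candidate(seed=seed, candidate=tok, cosine=sim)
                              for tok, sim in kept)
        out.append(clist)
    return out


def apply_review(lexicons: LexiconSet, reviewed: Iterable[CandidateList]) -> LexiconSet:
    """Fold accepted candidates into a new LexiconSet (monotone growth).

    Rejected and pending rows are ignored; duplicate accepts collapse (set
    semantics); an unknown topic name is an error.
    """
    updated = copy.deepcopy(lexicons)
    known = set(updated.topic_names)
    for clist in reviewed:
        if clist.topic_name not in known:
            raise KeyError(f"review references unknown topic {clist.topic_name!r}")
        lx = updated[clist.topic_name]
        for row in clist.rows:
            if row.decision == "accept" and row.candidate not in lx.keywords:
                lx.keywords.add(row.candidate)
                lx.provenance[row.candidate] = EXPANDED
    return updated


def write_worksheet(candidates: Iterable[CandidateList], path: str | Path) -> Path:
    """Serialize candidate lists as the review TSV worksheet."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(WORKSHEET_HEADER + "\n")
        for clist in candidates:
            for row in clist.rows:
                fh.write(f"{clist.topic_name}\t{row.seed}\t{row.candidate}"
                         f"\t{row.cosine:.4f}\t{row.decision}\n")
    return path


def read_worksheet(path: str | Path) -> list[CandidateList]:
    """Parse a (possibly hand-edited) review worksheet back into candidate lists."""
    path = Path(path)
    lists: dict[str, CandidateList] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != WORKSHEET_HEADER:
            raise ValueError(f"unexpected worksheet header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-separated fields")
            topic, seed, candidate, cosine, decision = parts
            clist = lists.setdefault(topic, CandidateList(topic_name=topic))
            clist.rows.append(Candidate(seed=seed, candidate=candidate,
                                        cosine=float(cosine), decision=decision))
    return list(lists.values())
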