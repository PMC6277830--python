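"""Exclusion filters: retweets, non-English posts, bot-authored accounts.

Each filter is a pure subset operation (idempotent, order-preserving). The
chain applies them in the study's order — retweets and non-English posts
first, then bot accounts — and reports attrition at each step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from hookahscope.records import Corpus, TweetRecord

RETWEET_PREFIX = "RT @"

# Optional hook: given a record with lang == "und", return True to keep it as
# English. Signature matches a langdetect-style callable adapter.
LanguageDetector = Callable[[TweetRecord], bool]


@dataclass(frozen=True)
class BotPolicy:
    """Account-level bot removal policy.

    threshold: accounts whose bot probability score is >= threshold are treated
    as social bots and all their tweets are dropped. 0.5 is the conventional
    midpoint of bot-probability scorers and the default here.
    missing_score_action: what to do with tweets from unscored accounts.
    """

    threshold: float = 0.5
    missing_score_action: str = "keep"

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError(f"bot threshold {self.threshold} outside [0, 1]")
        if self.missing_score_action not in ("keep", "drop"):
            raise ValueError("missing_score_action must be 'keep' or 'drop'")


@dataclass(frozen=True)
class FilterReport:
    """Attrition at each step of the filter chain."""

    n_input: int
    n_after_retweet: int
    n_after_language: int
    n_after_bot: int

    @property
    def n_retweets_removed(self) -> int:
        return self.n_input - self.n_after_retweet

    @property
    def n_non_english_removed(self) -> int:
        return self.n_after_retweet - self.n_after_language

    @property
    def n_bot_removed(self) -> int:
        return self.n_after_language - self.n_after_bot

    def __post_init__(self) -> None:
        if not (self.n_input >= self.n_after_retweet >= self.n_after_language >= self.n_after_bot >= 0):
            raise ValueError(f"inconsistent filter attrition: {self}")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_retweet": self.n_after_retweet,
            "n_after_language": self.n_after_language,
            "n_after_bot": self.n_after_bot,
            "n_retweets_removed": self.n_retweets_removed,
            "n_non_english_removed": self.n_non_english_removed,
            "n_bot_removed": self.n_bot_removed,
        }


def is_retweet(record: TweetRecord) -> bool:
    """Retweet by platform flag OR by the conventional "RT @" text prefix."""
    return record.is_retweet or record.text.startswith(RETWEET_PREFIX)


def remove_retweets(corpus: Corpus) -> Corpus:
    keep = [rec for rec in corpus if not is_retweet(rec)]
    return corpus.subset(keep, provenance=f"{corpus.provenance} | retweets removed")


def remove_non_english(corpus: Corpus, detector: Optional[LanguageDetector] = None) -> Corpus:
    """Keep records with lang == "en".

    Records with lang == "und" are resolved by the detector hook when one is
    supplied; with no hook they are kept, so results never silently depend on
    a third-party detector.
    """
    keep = []
    for rec in corpus:
        if rec.lang == "en":
            keep.append(rec)
        elif rec.lang == "und" and (detector is None or detector(rec)):
            keep.append(rec)
    return corpus.subset(keep, provenance=f"{corpus.provenance} | non-English removed")


def remove_bots(corpus: Corpus, policy: BotPolicy = BotPolicy()) -> Corpus:
    """Drop every tweet authored by an account flagged as a social bot.

    Removal is account-level: if any tweet of a user carries a score >= the
    threshold, all of that user's tweets are removed.
    """
    flagged = {
        rec.user_id
        for rec in corpus
        if rec.bot_score is not None and rec.bot_score >= policy.threshold
    }
    keep = []
    for rec in corpus:
        if rec.user_id in flagged:
            continue
        if rec.bot_score is None and policy.missing_score_action == "drop":
            continue
        keep.append(rec)
    return corpus.subset(keep, provenance=f"{corpus.provenance} | bots removed")


def run_filter_chain(corpus: Corpus, policy: BotPolicy = BotPolicy(),
                     detector: Optional[LanguageDetector] = None) -> tuple[Corpus, FilterReport]:
    """remove_bots ∘ remove_non_english ∘ remove_retweets, with attrition report."""
    after_rt = remove_retweets(corpus)
    after_lang = remove_non_english(after_rt, detector=detector)
    after_bot = remove_bots(after_lang, policy=policy)
    report = FilterReport(
        n_input=len(corpus),
        n_after_retweet=len(after_rt),
        n_after_language=len(after_lang),
        n_after_bot=len(after_bot),
    )
    return after_bot, report
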