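#!/usr/bin/env python
"""Apply the three exclusion filters and report attrition.

Retweets and non-English posts first, then tweets from accounts scored as
social bots (threshold 0.5, account-level). The attrition table is the
pipeline's primary audit trail.
"""

import json
from pathlib import Path

import hookahscope as hs

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    corpus_path = SCRATCH / "corpus.jsonl"
    if not corpus_path.exists():
        raise SystemExit("run analysis/01_simulate_corpus.py first")
    corpus = hs.read_corpus(corpus_path)
    filtered, report = hs.run_filter_chain(corpus, policy=hs.BotPolicy(threshold=0.5))
    hs.write_corpus(filtered, SCRATCH / "filtered.jsonl")
    (RESULTS / "filter_report.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n", "utf-8")
    print(f"input posts:            {report.n_input}")
    print(f"after retweet removal:  {report.n_after_retweet} (-{report.n_retweets_removed})")
    print(f"after language removal: {report.n_after_language} (-{report.n_non_english_removed})")
    print(f"after bot removal:      {report.n_after_bot} (-{report.n_bot_removed})")
    print(f"analytic sample: {len(filtered)} tweets from "
          f"{hs.corpus_stats(filtered).n_distinct_users} accounts")


if __name__ == "__main__":
    main()
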