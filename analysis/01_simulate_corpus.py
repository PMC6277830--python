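#!/usr/bin/env python
"""Generate the study-shaped synthetic corpus that the downstream steps analyze.

50,000 posts tracking the term "hookah": planted topic mixture at the
published prevalence profile, retweets, non-English posts, and bot accounts.
The raw corpus and ground truth go to scratch/ (large, regenerable); the
corpus summary table goes to results/.
"""

import json
from pathlib import Path

import hookahscope as hs

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 11
N_TWEETS = 50_000


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    config = hs.GeneratorConfig(n_tweets=N_TWEETS, seed=SEED)
    corpus, truth = hs.generate(config)
    hs.write_corpus(corpus, SCRATCH / "corpus.jsonl")
    (SCRATCH / "truth.json").write_text(json.dumps({
        "topic_names": truth.topic_names,
        "clean_ids": truth.clean_ids,
        "per_tweet": {tid: sorted(t.topics) for tid, t in truth.per_tweet.items()},
    }) + "\n", "utf-8")

    stats = hs.corpus_stats(corpus).to_dict()
    (RESULTS / "corpus_stats.json").write_text(json.dumps(stats, indent=2) + "\n", "utf-8")
    print(f"generated {stats['n_records']} posts from {stats['n_distinct_users']} accounts "
          f"(seed {SEED}); {len(truth.clean_ids)} are clean by construction")
    print(f"language histogram: {stats['language_histogram']}")
    print(f"wrote {SCRATCH / 'corpus.jsonl'} and {RESULTS / 'corpus_stats.json'}")


if __name__ == "__main__":
    main()
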