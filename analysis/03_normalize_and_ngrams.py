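#!/usr/bin/env python
"""Normalize the analytic sample and profile unigram/bigram frequencies.

The frequency tables are the topic-discovery surface: in the original
workflow they were rendered as word clouds and read by experts; here the
top-50 tables are exported directly.
"""

import json
from pathlib import Path

import hookahscope as hs

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    filtered_path = SCRATCH / "filtered.jsonl"
    if not filtered_path.exists():
        raise SystemExit("run analysis/02_filter_corpus.py first")
    corpus = hs.read_corpus(filtered_path)
    normalized = hs.normalize_corpus(corpus)
    with (SCRATCH / "normalized.jsonl").open("w", encoding="utf-8") as fh:
        for tw in normalized:
            fh.write(json.dumps({"tweet_id": tw.tweet_id, "tokens": list(tw.tokens)}) + "\n")

    for n, name in ((1, "unigrams"), (2, "bigrams")):
        table = hs.count_ngrams(normalized, n=n)
        top = hs.top_k(table, 50)
        with (RESULTS / f"{name}_top50.tsv").open("w", encoding="utf-8") as fh:
            fh.write("ngram\tcount\n")
            for ngram, count in top:
                fh.write(f"{ngram}\t{count}\n")
        print(f"{name}: {len(table)} distinct, top 5: "
              + ", ".join(f"{g} ({c})" for g, c in top[:5]))
    print(f"normalized {len(normalized)} tweets; tables under {RESULTS}")


if __name__ == "__main__":
    main()
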