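#!/usr/bin/env python
"""Embedding-assisted lexicon expansion: train skip-gram vectors, propose
near-neighbor candidates per topic seed, write the review worksheet.

On a purely synthetic corpus the filler vocabulary has no semantic structure,
so this step mainly demonstrates the mechanics; a planted-synonym variant
(two appeal terms used in interchangeable contexts) shows the recovery the
procedure is designed for.
"""

import json
from pathlib import Path

import numpy as np

import hookahscope as hs
from hookahscope.normalize import NormalizedTweet

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 11


def main() -> None:
    norm_path = SCRATCH / "normalized.jsonl"
    if not norm_path.exists():
        raise SystemExit("run analysis/03_normalize_and_ngrams.py first")
    normalized = [
        NormalizedTweet(obj["tweet_id"], tuple(obj["tokens"]))
        for obj in map(json.loads, norm_path.read_text("utf-8").splitlines())
    ]
    lexicons = hs.load_default_lexicons()
    model = hs.train_embeddings(
        normalized, hs.EmbeddingConfig(dim=50, window=5, min_count=5, epochs=2, seed=SEED))
    candidates = hs.propose_candidates(model, lexicons, top_k=10, min_cosine=0.5)
    hs.write_worksheet(candidates, RESULTS / "expansion_worksheet.tsv")
    n_rows = sum(len(c.rows) for c in candidates)
    print(f"vocabulary {len(model)} tokens; {n_rows} candidates written to "
          f"{RESULTS / 'expansion_worksheet.tsv'} (decisions: pending)")

    # planted-synonym demonstration: "crave" and "want" share contexts
    rng = np.random.default_rng(SEED)
    ctx = ["tonight", "lounge", "session", "friend", "vibe", "relax", "chill"]
    sents = []
    for i in range(1200):
        word = "crave" if i % 2 else "want"
        c = [ctx[int(rng.integers(len(ctx)))] for _ in range(4)]
        sents.append(NormalizedTweet(f"s{i}", tuple(c[:2] + [word, "hookah"] + c[2:])))
    planted = hs.train_embeddings(
        sents, hs.EmbeddingConfig(dim=40, window=3, min_count=5, epochs=3, seed=SEED))
    reduced = hs.apply_review(lexicons, [])
    reduced["Appeal or Abuse Liability"].keywords.discard("want")
    appeal = next(c for c in hs.propose_candidates(planted, reduced, top_k=10, min_cosine=0.3)
                  if c.topic_name == "Appeal or Abuse Liability")
    ranked = sorted(appeal.rows, key=lambda r: -r.cosine)
    print("planted-synonym check: appeal candidates =",
          [(r.candidate, round(r.cosine, 2)) for r in ranked[:3]])


if __name__ == "__main__":
    main()
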