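"""Skip-gram word embeddings with negative sampling, trained in-process.

The trainer is a plain numpy implementation of the skip-gram-with-negative-
sampling objective: each word predicts the words around it inside a sampled
window, against k noise words drawn from the unigram distribution raised to
the 3/4 power. Synonym-like tokens — tokens that occur in interchangeable
contexts — end up with high cosine similarity, which is all the lexicon
expansion stage needs.

Training is strictly sequential and seeded, so identical (corpus, config)
pairs yield identical vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from hookahscope.normalize import NormalizedTweet


@dataclass(frozen=True)
class EmbeddingConfig:
    """Skip-gram training hyperparameters.

    Defaults follow common practice for this model family: 100-dimensional
    vectors, symmetric window of 5, minimum token count 5, 5 epochs, 5
    negative samples, linearly decayed learning rate from 0.025.
    """

    dim: int = 100
    window: int = 5
    min_count: int = 5
    epochs: int = 5
    negative: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    seed: int = 0
    algorithm: str = "skip-gram"

    def __post_init__(self) -> None:
        if self.algorithm != "skip-gram":
            raise ValueError("only the skip-gram algorithm is implemented")
        if min(self.dim, self.window, self.epochs, self.negative) < 1 or self.min_count < 1:
            raise ValueError("dim, window, epochs, negative, min_count must be >= 1")


class EmbeddingModel:
    """Vocabulary plus one input vector per token."""

    def __init__(self, vocab: Sequence[str], vectors: np.ndarray, config: EmbeddingConfig):
        if len(vocab) != vectors.shape[0]:
            raise ValueError("one vector per vocabulary token required")
        self.vocab: list[str] = list(vocab)
        self.index: dict[str, int] = {tok: i for i, tok in enumerate(self.vocab)}
        self.vectors = vectors
        self.config = config
        norms = np.linalg.norm(vectors, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self._unit = vectors / norms

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __len__(self) -> int:
        return len(self.vocab)

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.index[token]]

    def cosine(self, a: str, b: str) -> float:
        return float(self._unit[self.index[a]] @ self._unit[self.index[b]])

    def most_similar(self, token: str, top_k: int = 10,
                     exclude: Iterable[str] = ()) -> list[tuple[str, float]]:
        """Nearest vocabulary neighbors by cosine, descending, ties lexicographic."""
        i = self.index[token]
        sims = self._unit @ self._unit[i]
        banned = set(exclude) | {token}
        ranked = sorted(
            ((self.vocab[j], float(sims[j])) for j in range(len(self.vocab))
             if self.vocab[j] not in banned),
            key=lambda item: (-item[1], item[0]),
        )
        return ranked[:top_k]


def _build_vocab(sentences: list[tuple[str, ...]], min_count: int) -> tuple[list[str], np.ndarray]:
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    # frequency-descending, then lexicographic: a stable, reproducible ordering
    vocab = sorted((t for t, c in counts.items() if c >= min_count),
                   key=lambda t: (-counts[t], t))
    return vocab, np.array([counts[t] for t in vocab], dtype=np.float64)


def train_embeddings(tweets: Iterable[NormalizedTweet] | Iterable[Sequence[str]],
                     config: EmbeddingConfig = EmbeddingConfig()) -> EmbeddingModel:
    """Train skip-gram embeddings on normalized token sequences.

    Tokens occurring fewer than ``min_count`` times never enter the
    vocabulary. Raises if nothing survives the count threshold.
    """
    sentences: list[tuple[str, ...]] = []
    for item in tweets:
        toks = tuple(item.tokens) if isinstance(item, NormalizedTweet) else tuple(item)
        if toks:
            sentences.append(toks)
    if not sentences:
        raise ValueError("empty corpus: nothing to train on")
    vocab, counts = _build_vocab(sentences, config.min_count)
    if not vocab:
        raise ValueError("empty effective vocabulary (min_count too high?)")
    index = {t: i for i, t in enumerate(vocab)}
    encoded = [np.array([index[t] for t in sent if t in index], dtype=np.int64)
               for sent in sentences]
    encoded = [s for s in encoded if len(s) > 1]

    rng = np.random.default_rng(config.seed)
    n_vocab = len(vocab)
    w_in = (rng.random((n_vocab, config.dim)) - 0.5) / config.dim
    w_out = np.zeros((n_vocab, config.dim))

    noise = counts ** 0.75
    noise /= noise.sum()

    # pre-drawn negative-sample buffer, refilled as needed (keeps sampling
    # out of the inner loop while staying fully deterministic)
    buf_size = 1 << 16
    neg_buf = rng.choice(n_vocab, size=buf_size, p=noise)
    neg_pos = 0

    def negatives(k: int) -> np.ndarray:
        nonlocal neg_buf, neg_pos
        if neg_pos + k > buf_size:
            neg_buf = rng.choice(n_vocab, size=buf_size, p=noise)
            neg_pos = 0
        out = neg_buf[neg_pos:neg_pos + k]
        neg_pos += k
        return out

    total_words = sum(len(s) for s in encoded) * config.epochs
    processed = 0
    lr0, lr_min = config.learning_rate, config.min_learning_rate
    k = config.negative
    labels = np.zeros(k + 1)
    labels[0] = 1.0

    for _epoch in range(config.epochs):
        for sent in encoded:
            n = len(sent)
            reduced = rng.integers(1, config.window + 1, size=n)
            for i in range(n):
                lr = max(lr_min, lr0 * (1.0 - processed / max(1, total_words)))
                processed += 1
                b = reduced[i]
                lo, hi = max(0, i - b), min(n, i + b + 1)
                center = sent[i]
                h = w_in[center]
                for j in range(lo, hi):
                    if j == i:
                        continue
                    targets = np.empty(k + 1, dtype=np.int64)
                    targets[0] = sent[j]
                    targets[1:] = negatives(k)
                    v = w_out[targets]
                    scores = v @ h
                    sig = 1.0 / (1.0 + np.exp(-np.clip(scores, -30, 30)))
                    g = (sig - labels) * lr
                    h_grad = g @ v
                    np.add.at(w_out, targets, -g[:, None] * h)
                    h -= h_grad  # in-place view update of w_in[center]
    return EmbeddingModel(vocab=vocab, vectors=w_in, config=config)
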