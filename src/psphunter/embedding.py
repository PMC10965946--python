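"""Word2vec sequence embeddings over nonoverlapping 3-gram "sentences".

Each protein sequence is read in its three frames; every frame becomes one
sentence of nonoverlapping 3-gram words, so the three sentences together
cover all L-2 consecutive 3-grams.  A continuous-bag-of-words (CBOW)
word2vec model with negative sampling is trained on such a corpus, and a
protein is embedded as the mean vector of its in-vocabulary 3-grams.

The trainer is a compact, seeded, single-worker implementation in numpy:
stochastic gradient descent over (context -> target) pairs with a linearly
decaying learning rate and a unigram^(3/4) negative-sampling distribution.
Given identical corpus, hyperparameters and seed it is bitwise
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .io import AA_ORDER, ProteinRecord

logger = logging.getLogger("psphunter")

_CANONICAL = set(AA_ORDER)


def sequence_ngrams(seq: str, n: int = 3) -> list[str]:
    """All consecutive n-grams of a sequence, skipping any containing a
    noncanonical letter (X)."""
    return [seq[i:i + n] for i in range(len(seq) - n + 1)
            if set(seq[i:i + n]) <= _CANONICAL]


def build_corpus(records: list[ProteinRecord], n: int = 3) -> list[list[str]]:
    """Three sentences per protein: nonoverlapping n-grams starting at
    offsets 0, 1 and 2; trailing residues shorter than n are dropped.
    Words containing noncanonical letters are omitted."""
    if not records:
        raise ValueError("build_corpus needs at least one record")
    corpus: list[list[str]] = []
    for rec in records:
        for offset in range(n):
            sentence = [
                rec.sequence[i:i + n]
                for i in range(offset, len(rec.sequence) - n + 1, n)
            ]
            sentence = [w for w in sentence if set(w) <= _CANONICAL]
            if not sentence:
                logger.debug("empty frame %d for %s (length %d)",
                             offset, rec.id, rec.length)
            corpus.append(sentence)
    return corpus


@dataclass
class EmbeddingModel:
    """A trained 3-gram embedding: vocabulary plus one vector per word."""

    vocab: dict[str, int]
    vectors: np.ndarray  # V x dim
    dim: int = 60
    window: int = 70
    epochs: int = 5
    seed: int = 0
    pooling: str = "mean"
    config: dict = field(default_factory=dict)

    def __contains__(self, word: str) -> bool:
        return word in self.vocab

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.vocab[word]]


def fit_embedding(
    corpus: list[list[str]],
    dim: int = 60,
    window: int = 70,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    min_count: int = 1,
    seed: int = 0,
) -> EmbeddingModel:
    """Train a CBOW word2vec model with negative sampling.

    ``window`` is the maximum distance (in words) between the predicted word
    and a context word.  Training order is the fixed corpus order, so the
    result is deterministic for a given seed.
    """
    counts: dict[str, int] = {}
    for sentence in corpus:
        for w in sentence:
            counts[w] = counts.get(w, 0) + 1
    vocab_words = sorted(w for w, c in counts.items() if c >= min_count)
    if not vocab_words:
        raise ValueError("empty vocabulary: corpus has no eligible words")
    vocab = {w: i for i, w in enumerate(vocab_words)}
    V = len(vocab)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    freq = np.array([counts[w] for w in vocab_words], dtype=float) ** 0.75
    noise_p = freq / freq.sum()

    sentences = [np.array([vocab[w] for w in s if w in vocab], dtype=np.intp)
                 for s in corpus]
    total_words = sum(len(s) for s in sentences) * epochs
    if total_words == 0:
        raise ValueError("corpus contains only out-of-vocabulary words")

    processed = 0
    for _epoch in range(epochs):
        for sent in sentences:
            n = len(sent)
            if n < 2:
                processed += n
                continue
            neg = rng.choice(V, size=(n, negative), p=noise_p)
            for t in range(n):
                lr = max(min_alpha,
                         alpha * (1.0 - processed / total_words))
                processed += 1
                lo, hi = max(0, t - window), min(n, t + window + 1)
                ctx = np.concatenate([sent[lo:t], sent[t + 1:hi]])
                if ctx.size == 0:
                    continue
                h = W_in[ctx].mean(axis=0)
                targets = np.concatenate(([sent[t]], neg[t]))
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                out = W_out[targets]
                g = (labels - expit(out @ h)) * lr
                err = g @ out
                W_out[targets] += np.outer(g, h)
                W_in[ctx] += err / ctx.size
    return EmbeddingModel(
        vocab=vocab, vectors=W_in, dim=dim, window=window, epochs=epochs,
        seed=seed,
        config={"negative": negative, "alpha": alpha, "min_alpha": min_alpha,
                "min_count": min_count, "architecture": "cbow"},
    )


def embed_sequence(seq: str, model: EmbeddingModel,
                   pooling: str | None = None) -> np.ndarray:
    """Pool the vectors of all in-vocabulary 3-grams of a sequence.

    Default pooling is the unweighted mean; ``sum`` is available as an
    alternative.  A sequence whose 3-grams are all out of vocabulary maps to
    the zero vector (warned).
    """
    if len(seq) < 3:
        raise ValueError("embed_sequence needs length >= 3")
    pooling = pooling or model.pooling
    idx = [model.vocab[g] for g in sequence_ngrams(seq) if g in model.vocab]
    if not idx:
        logger.warning("all 3-grams out of vocabulary; zero embedding")
        return np.zeros(model.dim)
    vecs = model.vectors[np.asarray(idx, dtype=np.intp)]
    if pooling == "mean":
        return vecs.mean(axis=0)
    if pooling == "sum":
        return vecs.sum(axis=0)
    raise ValueError(f"unknown pooling {pooling!r}")
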