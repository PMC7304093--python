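"""Word embeddings: skip-gram with negative sampling, plus text-format IO.

The recurrent classifier consumes 100-dimensional word vectors.  In the
original setting those come from a word2vec model of a large national
reference corpus; this module provides (a) a self-contained skip-gram
negative-sampling (SGNS) trainer adequate for synthetic corpora and small
user corpora, and (b) a loader/saver for the standard word2vec text
format (``term v1 … v100`` per line), so externally trained vectors can
be dropped in.

The trainer is plain numpy and deterministic for a fixed seed.  It is not
a performance-tuned replacement for a dedicated embedding library — none
is assumed to be installed — but distributionally separated toy corpora
come out with the expected cosine structure within a few epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .textprep import TokenSequence

__all__ = [
    "EmbeddingTable",
    "learn_embeddings",
    "vectorize",
    "save_embeddings",
    "load_embeddings",
    "cosine",
]


@dataclass(frozen=True)
class EmbeddingTable:
    """Term -> real vector of fixed dimension."""

    dim: int
    vectors: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        for term, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise ValueError(
                    f"vector of {term!r} has shape {vec.shape}, expected ({self.dim},)"
                )

    def __contains__(self, term: str) -> bool:
        return term in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)


def learn_embeddings(
    corpus: Sequence[TokenSequence],
    dim: int = 100,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    min_count: int = 1,
    negative: int = 5,
    lr: float = 0.025,
) -> EmbeddingTable:
    """Train SGNS embeddings on a tokenized corpus.

    Every term occurring at least ``min_count`` times receives a vector.
    Deterministic for a fixed seed.  Raises on an empty corpus.
    """
    if not corpus or all(len(seq) == 0 for seq in corpus):
        raise ValueError("cannot learn embeddings from an empty corpus")
    rng = np.random.default_rng(seed)

    counts: dict[str, int] = {}
    for seq in corpus:
        for tok in seq:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError(f"no term reaches min_count={min_count}")
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    # unigram^0.75 negative-sampling distribution
    freq = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    neg_p = freq / freq.sum()

    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    # center/context pair list (fixed, order shuffled per epoch)
    pairs: list[tuple[int, int]] = []
    for seq in corpus:
        ids = [index[t] for t in seq.tokens if t in index]
        for i, c in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((c, ids[j]))
    if not pairs:  # single-token documents only: nothing to predict
        return EmbeddingTable(dim, {t: W_in[index[t]].copy() for t in vocab})

    pair_arr = np.array(pairs, dtype=np.int64)
    for _ in range(epochs):
        order = rng.permutation(len(pair_arr))
        negs = rng.choice(V, size=(len(pair_arr), negative), p=neg_p)
        for k, row in enumerate(order):
            center, context = pair_arr[row]
            targets = np.concatenate(([context], negs[k]))
            labels = np.zeros(len(targets))
            labels[0] = 1.0
            v = W_in[center]
            u = W_out[targets]
            scores = 1.0 / (1.0 + np.exp(-u @ v))
            g = (scores - labels) * lr
            W_in[center] = v - g @ u
            W_out[targets] = u - np.outer(g, v)
    return EmbeddingTable(dim, {t: W_in[index[t]].copy() for t in vocab})


def vectorize(seq: TokenSequence, table: EmbeddingTable) -> list[np.ndarray]:
    """Ordered vectors of a token sequence; out-of-vocabulary -> zero vector."""
    zero = np.zeros(table.dim)
    return [
        np.asarray(table.vectors[t], dtype=float) if t in table else zero
        for t in seq.tokens
    ]


def cosine(table: EmbeddingTable, a: str, b: str) -> float:
    """Cosine similarity between two in-vocabulary terms."""
    va, vb = table.vectors[a], table.vectors[b]
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    if denom == 0:
        return 0.0
    return float(va @ vb / denom)


def save_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """word2vec text format with a ``count dim`` header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dim}\n")
        for term in sorted(table.vectors):
            vec = " ".join(repr(float(x)) for x in table.vectors[term])
            fh.write(f"{term} {vec}\n")


def load_embeddings(path: str | Path) -> EmbeddingTable:
    with open(path, encoding="utf-8-sig") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: expected 'count dim' header")
        count, dim = int(header[0]), int(header[1])
        vectors = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}: bad vector line for {parts[0]!r}")
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(vectors) != count:
        raise ValueError(f"{path}: header promises {count} vectors, found {len(vectors)}")
    return EmbeddingTable(dim, vectors)
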