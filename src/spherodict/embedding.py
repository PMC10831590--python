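"""Word embeddings for short clinical notes: CBOW training and cosine queries.

The continuous bag-of-words (CBOW) objective predicts a centre word from the
mean of its context vectors; training uses negative sampling against a
unigram^0.75 noise distribution.  The trainer is single-threaded and fully
seeded, so a fixed corpus + seed yields byte-identical vectors — a property
the dictionary-building workflow relies on for auditability.

Similarity is always cosine; *distance* means ``1 - cosine_similarity``
(range [0, 2]), the convention used throughout spherical dictionary
enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EmbeddingModel",
    "train_embedding",
    "cosine_similarity",
    "cosine_distance",
]

#: Neighbour-list defaults: up to 50 candidates, each seen at least 10 times.
DEFAULT_N_NEIGHBORS = 50
DEFAULT_MIN_FREQ = 10


class UnknownWordError(KeyError):
    """A query word has no embedding vector."""

    def __init__(self, word: str):
        super().__init__(word)
        self.word = word

    def __str__(self) -> str:  # KeyError quotes repr; keep the message plain
        return f"word {self.word!r} is not in the embedding vocabulary"


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-norm vector has no direction for cosine similarity")
    return v / n


@dataclass
class EmbeddingModel:
    """Vocabulary of word vectors plus corpus frequencies.

    Attributes
    ----------
    words : list of vocabulary words, index-aligned with ``matrix`` rows.
    matrix : (n_words, dim) float array of word vectors.
    freqs : word -> corpus frequency.
    metadata : training provenance (dim, epochs, window, seed, ...).
    """

    words: list[str]
    matrix: np.ndarray
    freqs: dict[str, int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {w: i for i, w in enumerate(self.words)}
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.words):
            raise ValueError("matrix rows must align with the word list")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_vectors(
        cls,
        vectors: Mapping[str, Sequence[float]],
        freqs: Mapping[str, int] | None = None,
        **metadata,
    ) -> "EmbeddingModel":
        """Build a model from an explicit word -> vector mapping.

        Useful for hand-set toy geometries in tests and documentation.
        Missing frequencies default to 1.
        """
        words = list(vectors)
        matrix = np.asarray([vectors[w] for w in words], dtype=float)
        f = {w: (freqs.get(w, 1) if freqs else 1) for w in words}
        return cls(words, matrix, f, dict(metadata))

    # -- lookups ----------------------------------------------------------
    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __len__(self) -> int:
        return len(self.words)

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.matrix[self._index[word]]
        except KeyError:
            raise UnknownWordError(word) from None

    def _resolve(self, item) -> np.ndarray:
        if isinstance(item, str):
            return self.vector(item)
        return np.asarray(item, dtype=float)

    # -- similarity -------------------------------------------------------
    def cosine_similarity(self, a, b) -> float:
        """Cosine of the angle between two words or raw vectors, in [-1, 1]."""
        return float(np.clip(np.dot(_unit(self._resolve(a)), _unit(self._resolve(b))), -1.0, 1.0))

    def cosine_distance(self, a, b) -> float:
        """``1 - cosine_similarity``; 0 for parallel, 2 for opposite vectors."""
        return 1.0 - self.cosine_similarity(a, b)

    def nearest_neighbors(
        self,
        query: str | Iterable[str],
        n: int = DEFAULT_N_NEIGHBORS,
        min_freq: int = DEFAULT_MIN_FREQ,
    ) -> list[tuple[str, float]]:
        """Words most similar to a query word or word set.

        Multi-word queries are ranked against the centroid of the query
        vectors (the whole seed list acts as the query).  Query words are
        excluded from the result; candidates below ``min_freq`` corpus
        occurrences are dropped.  Ties break by (similarity desc,
        frequency desc, word asc) so the ordering is deterministic.

        Returns at most ``n`` ``(word, similarity)`` pairs, descending.
        """
        if isinstance(query, str):
            query_words = [query]
        else:
            query_words = list(query)
        embedded = [w for w in query_words if w in self._index]
        if not embedded:
            raise UnknownWordError(
                query_words[0] if query_words else "<empty query>"
            )
        centroid = _unit(np.mean([self.vector(w) for w in embedded], axis=0))

        norms = np.linalg.norm(self.matrix, axis=1)
        safe = norms > 0
        sims = np.full(len(self.words), -np.inf)
        sims[safe] = (self.matrix[safe] / norms[safe, None]) @ centroid

        exclude = set(query_words)
        scored = [
            (w, float(np.clip(sims[i], -1.0, 1.0)))
            for i, w in enumerate(self.words)
            if w not in exclude
            and safe[i]
            and self.freqs.get(w, 0) >= min_freq
        ]
        scored.sort(key=lambda t: (-t[1], -self.freqs.get(t[0], 0), t[0]))
        return scored[:n]

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the standard word2vec text format (header ``count dim``)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.words)} {self.dim}\n")
            for w, row in zip(self.words, self.matrix):
                fh.write(w + " " + " ".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def load(
        cls, path: str | Path, freqs: Mapping[str, int] | None = None
    ) -> "EmbeddingModel":
        """Read the word2vec text format written by :meth:`save`."""
        with open(path, encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            words, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                words.append(parts[0])
                rows.append([float(x) for x in parts[1 : dim + 1]])
        if len(words) != n:
            raise ValueError(f"header promised {n} words, file holds {len(words)}")
        f = {w: (freqs.get(w, 1) if freqs else 1) for w in words}
        return cls(words, np.asarray(rows), f)


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Cosine similarity of two raw vectors (module-level convenience)."""
    return float(
        np.clip(np.dot(_unit(np.asarray(a, float)), _unit(np.asarray(b, float))), -1, 1)
    )


def cosine_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """``1 - cosine_similarity`` of two raw vectors."""
    return 1.0 - cosine_similarity(a, b)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embedding(
    corpus: Sequence[Sequence[str]],
    dim: int = 300,
    epochs: int = 100,
    window: int = 5,
    min_count: int = 1,
    seed: int = 0,
    negative: int = 5,
    alpha: float = 0.05,
    sample: float | None = 1e-3,
) -> EmbeddingModel:
    """Train CBOW word vectors with negative sampling.

    Parameters
    ----------
    corpus
        Per-visit token sequences (already lowercased).
    dim
        Embedding dimension; default 300.
    epochs
        Full passes over the corpus; default 100 — short notes carry little
        context per token, so many passes are needed for stable geometry.
    window
        Symmetric context half-width in tokens.
    min_count
        Words rarer than this are skipped during training (default 1:
        everything is trained; frequency filtering happens at query time).
    seed
        Seeds initialisation and negative sampling; with single-threaded
        updates this makes training exactly reproducible.
    negative
        Noise words per positive example.
    alpha
        Initial learning rate, decayed linearly to 1e-4 of its start.
    sample
        Frequent-word subsampling threshold: tokens with corpus frequency
        above this are randomly thinned per epoch (keep probability
        ``(sqrt(f/sample)+1)*sample/f``).  Without it, very frequent words
        that always co-occur can end up *anti*-aligned, because a word
        never co-occurs with itself.  None disables subsampling.

    Returns
    -------
    EmbeddingModel with training metadata recorded.
    """
    if dim < 2:
        raise ValueError(f"embedding dimension must be >= 2, got {dim}")
    from collections import Counter

    counts = Counter()
    for sent in corpus:
        counts.update(sent)
    vocab = [w for w, c in sorted(counts.items()) if c >= min_count]
    if len(vocab) < 2:
        raise ValueError(
            "corpus too small: need at least 2 distinct retained words, "
            f"got {len(vocab)}"
        )
    index = {w: i for i, w in enumerate(vocab)}
    sents = [
        np.array([index[w] for w in sent if w in index], dtype=np.int64)
        for sent in corpus
    ]
    sents = [s for s in sents if len(s) >= 2]
    if not sents:
        raise ValueError("corpus too small: no sentence has 2 retained tokens")

    rng = np.random.default_rng(seed)
    n = len(vocab)
    w_in = (rng.random((n, dim)) - 0.5) / dim
    w_out = np.zeros((n, dim))

    # unigram^0.75 noise distribution, as cumulative table for fast sampling
    noise = np.array([counts[w] for w in vocab], dtype=float) ** 0.75
    noise_cum = np.cumsum(noise / noise.sum())

    # per-word keep probability for frequent-word subsampling
    keep = np.ones(n)
    if sample:
        total_tokens = sum(counts[w] for w in vocab)
        freqs_arr = np.array([counts[w] / total_tokens for w in vocab])
        hot = freqs_arr > sample
        keep[hot] = (np.sqrt(freqs_arr[hot] / sample) + 1) * sample / freqs_arr[hot]

    total_steps = epochs * sum(len(s) for s in sents)
    step = 0
    min_alpha = alpha * 1e-4
    for _ in range(epochs):
        for full_sent in sents:
            if sample:
                sent = full_sent[rng.random(len(full_sent)) < keep[full_sent]]
            else:
                sent = full_sent
            for t in range(len(sent)):
                lr = max(min_alpha, alpha * (1 - step / total_steps))
                step += 1
                lo, hi = max(0, t - window), min(len(sent), t + window + 1)
                ctx = np.concatenate([sent[lo:t], sent[t + 1 : hi]])
                if len(ctx) == 0:
                    continue
                h = w_in[ctx].mean(axis=0)
                neg = np.searchsorted(noise_cum, rng.random(negative))
                neg = neg[neg != sent[t]]  # a word is not its own noise
                targets = np.concatenate([[sent[t]], neg])
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                out = w_out[targets]
                g = (labels - _sigmoid(out @ h)) * lr
                grad_h = g @ out
                w_out[targets] += np.outer(g, h)
                w_in[ctx] += grad_h / len(ctx)

    meta = {
        "dim": dim,
        "epochs": epochs,
        "window": window,
        "min_count": min_count,
        "seed": seed,
        "negative": negative,
        "alpha": alpha,
        "sample": sample,
        "algorithm": "cbow-negative-sampling",
    }
    freqs = {w: counts[w] for w in vocab}
    return EmbeddingModel(vocab, w_in, freqs, meta)
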