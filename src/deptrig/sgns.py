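"""Skip-gram with negative sampling over arbitrary (word, context) pairs.

This is the word2vecf generalisation of skip-gram: the training signal is
any stream of (word, context) pairs, so the same trainer learns
dependency-based embeddings (syntactic contexts) and bag-of-words
embeddings (linear-window contexts).  For a positive pair (w, c) and K
noise contexts c_1..c_K drawn from the context unigram distribution raised
to the 3/4 power, the per-pair loss is

    L = -log sigma(w.c) - sum_k log sigma(-w.c_k)

minimised by SGD with a linearly decaying learning rate.  Word vectors are
initialised uniformly in [-0.5/size, 0.5/size] and context vectors at zero
(the word2vec convention).  Training is single-threaded and fully seeded:
the same seed and pair stream give bitwise-identical matrices.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .contexts import ContextPair

__all__ = [
    "Vocabulary",
    "EmbeddingMatrix",
    "SGNSConfig",
    "build_vocab",
    "sgns_pair_objective",
    "train_sgns",
    "most_similar",
    "write_embeddings",
    "read_embeddings",
]


@dataclass
class Vocabulary:
    """Items ordered by descending count (ties lexicographic), with counts
    and a string -> position index."""

    items: list[str]
    counts: list[int]
    min_count: int = 1
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {w: i for i, w in enumerate(self.items)}
        if len(self.index) != len(self.items):
            raise ValueError("duplicate vocabulary items")

    @classmethod
    def from_counts(cls, counts: Counter | dict[str, int], min_count: int = 1) -> "Vocabulary":
        kept = [(w, n) for w, n in counts.items() if n >= min_count]
        kept.sort(key=lambda wn: (-wn[1], wn[0]))
        if not kept:
            raise ValueError(f"no items survive min_count={min_count}")
        return cls(items=[w for w, _ in kept], counts=[n for _, n in kept], min_count=min_count)

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def __getitem__(self, word: str) -> int:
        return self.index[word]


@dataclass
class EmbeddingMatrix:
    """Vocabulary-indexed dense vectors (one row per vocabulary item)."""

    vocab: Vocabulary
    vectors: np.ndarray

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocab):
            raise ValueError("row count does not match vocabulary size")

    @property
    def size(self) -> int:
        return self.vectors.shape[1]

    def get(self, word: str) -> np.ndarray:
        return self.vectors[self.vocab[word]]


@dataclass
class SGNSConfig:
    size: int = 200
    negatives: int = 5
    epochs: int = 20
    initial_lr: float = 0.025
    min_lr_factor: float = 1e-4  # final lr = initial_lr * min_lr_factor
    subsample_threshold: float | None = None
    seed: int = 1
    min_count_word: int = 10
    min_count_context: int = 10
    chunk: int = 512  # pairs per vectorised update step

    def __post_init__(self) -> None:
        if self.size < 1 or self.negatives < 1:
            raise ValueError("size and negatives must be >= 1")


class SGNSResult(NamedTuple):
    word: EmbeddingMatrix
    context: EmbeddingMatrix
    epoch_loss: list[float]


def build_vocab(
    pairs: Iterable[ContextPair], min_count_word: int = 10, min_count_context: int = 10
) -> tuple[Vocabulary, Vocabulary]:
    """Separate word-side and context-side vocabularies with independent
    frequency thresholds; pairs with a filtered item are simply dropped from
    training later."""
    wc: Counter = Counter()
    cc: Counter = Counter()
    for p in pairs:
        wc[p.word] += 1
        cc[p.context] += 1
    return (
        Vocabulary.from_counts(wc, min_count_word),
        Vocabulary.from_counts(cc, min_count_context),
    )


def _log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return -np.logaddexp(0.0, -x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def sgns_pair_objective(
    w_vec: np.ndarray, c_vec: np.ndarray, negative_c_vecs: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Loss and exact gradients for one positive pair and its K negatives.

    Returns ``(loss, grad_w, grad_c, grad_negs)`` with ``grad_negs`` shaped
    like ``negative_c_vecs`` (K x size).
    """
    negs = np.atleast_2d(negative_c_vecs)
    s_pos = float(w_vec @ c_vec)
    s_neg = negs @ w_vec
    loss = float(-_log_sigmoid(s_pos) - np.sum(_log_sigmoid(-s_neg)))
    g_pos = _sigmoid(np.array(s_pos)) - 1.0  # dL/d s_pos
    g_neg = _sigmoid(s_neg)  # dL/d s_neg_k
    grad_w = g_pos * c_vec + g_neg @ negs
    grad_c = g_pos * w_vec
    grad_negs = g_neg[:, None] * w_vec[None, :]
    return loss, grad_w, grad_c, grad_negs


def _encode_pairs(
    pairs: Sequence[ContextPair], wv: Vocabulary, cv: Vocabulary
) -> tuple[np.ndarray, np.ndarray]:
    wi, ci = [], []
    for p in pairs:
        a = wv.index.get(p.word)
        b = cv.index.get(p.context)
        if a is not None and b is not None:
            wi.append(a)
            ci.append(b)
    return np.asarray(wi, dtype=np.int64), np.asarray(ci, dtype=np.int64)


def train_sgns(
    pairs: Sequence[ContextPair],
    config: SGNSConfig,
    vocabs: tuple[Vocabulary, Vocabulary] | None = None,
) -> SGNSResult:
    """Train word and context matrices by seeded SGD over shuffled pairs.

    Negatives come from the context unigram distribution ** 0.75.  Pairs are
    processed in small contiguous chunks with vectorised gradient updates;
    this is deterministic for a fixed seed.  ``epochs=0`` returns the
    initial matrices untouched.
    """
    if vocabs is None:
        vocabs = build_vocab(pairs, config.min_count_word, config.min_count_context)
    wv, cv = vocabs
    rng = np.random.default_rng(config.seed)
    W = (rng.random((len(wv), config.size)) - 0.5) / config.size
    C = np.zeros((len(cv), config.size))

    wi, ci = _encode_pairs(pairs, wv, cv)
    n_pairs = wi.size
    epoch_loss: list[float] = []
    if n_pairs == 0 or config.epochs == 0:
        return SGNSResult(EmbeddingMatrix(wv, W), EmbeddingMatrix(cv, C), epoch_loss)

    noise = np.asarray(cv.counts, dtype=np.float64) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    keep_prob = None
    if config.subsample_threshold is not None:
        counts = np.bincount(wi, minlength=len(wv)).astype(np.float64)
        freq = counts / counts.sum()
        t = config.subsample_threshold
        with np.errstate(divide="ignore", invalid="ignore"):
            keep_prob = np.where(freq > 0, np.sqrt(t / np.maximum(freq, 1e-300)) + t / np.maximum(freq, 1e-300), 1.0)
        keep_prob = np.minimum(keep_prob, 1.0)

    total = n_pairs * config.epochs
    done = 0
    lr0 = config.initial_lr
    lr_min = lr0 * config.min_lr_factor
    K = config.negatives
    for _epoch in range(config.epochs):
        order = rng.permutation(n_pairs)
        if keep_prob is not None:
            mask = rng.random(n_pairs) < keep_prob[wi[order]]
            order = order[mask]
        loss_sum = 0.0
        n_seen = 0
        for lo in range(0, order.size, config.chunk):
            sel = order[lo : lo + config.chunk]
            B = sel.size
            iw = wi[sel]
            ic = ci[sel]
            ineg = np.minimum(
                np.searchsorted(noise_cdf, rng.random((B, K))), len(noise_cdf) - 1
            )
            lr = max(lr_min, lr0 * (1.0 - done / total))
            Ww = W[iw]
            Cp = C[ic]
            Cn = C[ineg]
            s_pos = np.einsum("bd,bd->b", Ww, Cp)
            s_neg = np.einsum("bd,bkd->bk", Ww, Cn)
            loss_sum += float(-np.sum(_log_sigmoid(s_pos)) - np.sum(_log_sigmoid(-s_neg)))
            g_pos = _sigmoid(s_pos) - 1.0
            g_neg = _sigmoid(s_neg)
            grad_w = g_pos[:, None] * Cp + np.einsum("bk,bkd->bd", g_neg, Cn)
            np.add.at(W, iw, -lr * grad_w)
            np.add.at(C, ic, -lr * g_pos[:, None] * Ww)
            np.add.at(
                C,
                ineg.reshape(-1),
                (-lr * g_neg[:, :, None] * Ww[:, None, :]).reshape(-1, config.size),
            )
            done += B
            n_seen += B
        epoch_loss.append(loss_sum / max(n_seen, 1))
        if not np.isfinite(epoch_loss[-1]):
            raise FloatingPointError(f"non-finite training loss at epoch {_epoch + 1}")
    if not (np.isfinite(W).all() and np.isfinite(C).all()):
        raise FloatingPointError("non-finite entries in trained matrices")
    return SGNSResult(EmbeddingMatrix(wv, W), EmbeddingMatrix(cv, C), epoch_loss)


def most_similar(emb: EmbeddingMatrix, word: str, k: int = 10) -> list[tuple[str, float]]:
    """Top-k neighbours by cosine similarity, query excluded, ties broken by
    vocabulary order."""
    if word not in emb.vocab:
        raise KeyError(f"unknown word {word!r}")
    q = emb.get(word)
    norms = np.linalg.norm(emb.vectors, axis=1)
    qn = np.linalg.norm(q)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = emb.vectors @ q / np.where(norms * qn > 0, norms * qn, np.inf)
    cos = np.nan_to_num(cos, nan=0.0)
    order = np.lexsort((np.arange(len(cos)), -cos))  # descending cosine, stable by index
    qi = emb.vocab[word]
    out = [(emb.vocab.items[i], float(cos[i])) for i in order if i != qi]
    return out[:k]


def write_embeddings(emb: EmbeddingMatrix, precision: int = 6) -> str:
    """word2vec text format: header ``count dim`` then one row per word."""
    lines = [f"{len(emb.vocab)} {emb.size}"]
    for w, row in zip(emb.vocab.items, emb.vectors):
        lines.append(w + " " + " ".join(f"{x:.{precision}f}" for x in row))
    return "\n".join(lines) + "\n"


def read_embeddings(text: str) -> EmbeddingMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty embedding file")
    header = lines[0].split()
    if len(header) != 2:
        raise ValueError("malformed header, expected 'count dim'")
    count, dim = int(header[0]), int(header[1])
    if len(lines) - 1 != count:
        raise ValueError(f"header promises {count} rows, file has {len(lines) - 1}")
    words, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split()
        if len(parts) != dim + 1:
            raise ValueError(f"line {lineno}: expected {dim + 1} columns, got {len(parts)}")
        words.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    vocab = Vocabulary(items=words, counts=[1] * len(words))
    return EmbeddingMatrix(vocab, np.asarray(rows))
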