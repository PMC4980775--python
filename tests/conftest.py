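"""Shared fixtures: small synthetic corpora and finite-difference oracles."""

from __future__ import annotations

import numpy as np
import pytest

from deptrig import SynthConfig, generate_corpus
from deptrig.classifier import ModelParams, TrainConfig, init_params, loss_and_gradients
from deptrig.sgns import EmbeddingMatrix, Vocabulary


@pytest.fixture(scope="session")
def small_corpus():
    """A fast, deterministic miniature of the benchmark corpus."""
    cfg = SynthConfig(
        n_unlabeled_sentences=400,
        n_labeled_documents=20,
        n_triggers=120,
        n_heldout_documents=5,
        seed=11,
    )
    return generate_corpus(cfg)


@pytest.fixture()
def tiny_embedding():
    """A 6-word embedding with easily recognisable rows."""
    vocab = Vocabulary(items=["alpha", "beta", "gamma", "delta", "epsi", "zeta"], counts=[6, 5, 4, 3, 2, 1])
    rng = np.random.default_rng(0)
    return EmbeddingMatrix(vocab, rng.normal(size=(6, 4)))


def rel_err(a: np.ndarray, b: np.ndarray) -> float:
    """Max-norm relative error.  Normalising by the array norms (not entry
    by entry) keeps finite-difference roundoff on near-zero entries from
    dominating: central differences carry ~eps*|f|/h absolute noise, which
    swamps any per-entry ratio for gradient entries near zero."""
    scale = max(float(np.max(np.abs(a))), float(np.max(np.abs(b))), 1e-8)
    return float(np.max(np.abs(np.asarray(a) - np.asarray(b)))) / scale


def numeric_grad(f, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function, entry by entry."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + h
        fp = f()
        x[i] = orig - h
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * h)
        it.iternext()
    return g


def random_small_net(
    rng: np.random.Generator,
) -> tuple[ModelParams, np.ndarray, np.ndarray]:
    """A tiny random classifier plus a random batch, for gradient checks."""
    size = int(rng.integers(2, 5))
    k = int(rng.integers(0, 2))
    n_layers = int(rng.integers(1, 3))
    hidden = int(rng.integers(3, 6))
    n_classes = int(rng.integers(2, 4))
    V = int(rng.integers(4, 8))
    vocab = Vocabulary(items=[f"w{i}" for i in range(V)], counts=[V - i for i in range(V)])
    emb = EmbeddingMatrix(vocab, rng.normal(scale=0.5, size=(V, size)))
    cfg = TrainConfig(k=k, layers=n_layers, hidden_size=hidden, dropout=0.0, seed=int(rng.integers(1 << 30)))
    classes = ["NONE"] + [f"C{i}" for i in range(n_classes - 1)]
    params = init_params(emb, classes, cfg, rng)
    # nudge biases off zero so no ReLU sits exactly at its kink (where the
    # central difference straddles the non-differentiable point)
    params.hidden = [
        (w, b + rng.normal(scale=0.1, size=b.shape)) for w, b in params.hidden
    ]
    params.out = (params.out[0], params.out[1] + rng.normal(scale=0.1, size=params.out[1].shape))
    B = int(rng.integers(1, 4))
    ids = rng.integers(0, V + 2, size=(B, 2 * k + 1))
    y = rng.integers(0, n_classes, size=B)
    return params, ids.astype(np.int64), y.astype(np.int64)


def check_classifier_gradients(rng: np.random.Generator, tol: float) -> None:
    params, ids, y = random_small_net(rng)

    def loss_only() -> float:
        return loss_and_gradients(params, ids, y, dropout=0.0)[0]

    _, gW, gh, gout = loss_and_gradients(params, ids, y, dropout=0.0)
    # embedding rows actually touched by the batch (PAD excluded by contract)
    num_W = numeric_grad(loss_only, params.W)
    num_W[params.pad_index] = 0.0
    assert rel_err(gW, num_W) <= tol
    for l, (w, b) in enumerate(params.hidden):
        assert rel_err(gh[l][0], numeric_grad(loss_only, w)) <= tol
        assert rel_err(gh[l][1], numeric_grad(loss_only, b)) <= tol
    assert rel_err(gout[0], numeric_grad(loss_only, params.out[0])) <= tol
    assert rel_err(gout[1], numeric_grad(loss_only, params.out[1])) <= tol
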