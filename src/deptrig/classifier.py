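"""Window-based neural trigger classifier.

Every non-stop-word token becomes one classification instance: the token
plus its k neighbours on each side (over the stop-word-filtered sequence,
PAD-filled at sentence edges).  The 2k+1 word indices are mapped through a
lookup table — the pre-trained embedding matrix W with PAD and UNK rows
appended — and concatenated into a (2k+1)*size input vector.  A stack of
fully connected ReLU layers with inverted dropout feeds a softmax output
over the trigger classes (plus NONE), trained by mini-batch gradient
descent with the AdaDelta update rule (no global learning rate).  In
non-static mode the embedding rows receive gradients too, fine-tuning the
representation to the labelled data; in static mode W is frozen.

All randomness (initialisation, shuffling, dropout masks) flows from a
single seed, so training is exactly reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .metrics import make_report, micro_f1, significant_classes
from .sgns import EmbeddingMatrix
from .standoff import NONE_LABEL
from .stopwords import STOPWORDS

__all__ = [
    "TriggerInstance",
    "TrainConfig",
    "ModelParams",
    "build_instances",
    "lookup_concat",
    "forward",
    "loss_and_gradients",
    "adadelta_update",
    "AdaDeltaState",
    "init_params",
    "fit",
    "predict",
    "FitResult",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TriggerInstance:
    """One example: a center token with its window of vocabulary indices."""

    doc_id: str
    sent_index: int
    token_index: int  # position in the *unfiltered* token sequence
    window_ids: tuple[int, ...]
    gold: str | None = None


@dataclass
class TrainConfig:
    k: int = 2  # window half-width
    layers: int = 4  # hidden layers
    hidden_size: int = 200
    dropout: float = 0.5
    batch: int = 256
    rho: float = 0.95  # AdaDelta decay
    eps: float = 1e-6  # AdaDelta conditioning constant
    max_epochs: int = 100
    patience: int = 10
    seed: int = 1
    static: bool = False  # freeze the embedding matrix
    significance_threshold: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.batch < 1:
            raise ValueError("batch must be >= 1")


@dataclass
class ModelParams:
    """Lookup table plus the fully connected stack.

    ``W`` has |vocab| + 2 rows: the embedding vocabulary, then PAD (all
    zeros, never trained), then UNK (mean embedding, trained in non-static
    mode).  ``classes`` fixes the output order; NONE is always first.
    """

    W: np.ndarray
    vocab_index: dict[str, int]
    pad_index: int
    unk_index: int
    hidden: list[tuple[np.ndarray, np.ndarray]]
    out: tuple[np.ndarray, np.ndarray]
    classes: list[str]
    k: int
    trainable_embedding: bool = True

    @property
    def size(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "ModelParams":
        return ModelParams(
            W=self.W.copy(),
            vocab_index=self.vocab_index,
            pad_index=self.pad_index,
            unk_index=self.unk_index,
            hidden=[(w.copy(), b.copy()) for w, b in self.hidden],
            out=(self.out[0].copy(), self.out[1].copy()),
            classes=list(self.classes),
            k=self.k,
            trainable_embedding=self.trainable_embedding,
        )


# ---------------------------------------------------------------------------
# instance construction


def build_instances(
    labeled_sentences: Iterable[tuple[str, int, Sequence[str], Sequence[str] | None]],
    vocab_index: Mapping[str, int],
    k: int,
    stopwords: frozenset[str] = STOPWORDS,
    pad_index: int | None = None,
    unk_index: int | None = None,
) -> list[TriggerInstance]:
    """Turn (doc_id, sent_index, forms, labels) sentences into instances.

    Stop-words are dropped from the sequence first; windows are taken over
    what remains, so a stop-word between two content words does not consume
    a context slot.  Words are lowercased before lookup; out-of-vocabulary
    words map to UNK and window positions beyond the sentence to PAD.
    """
    V = len(vocab_index)
    pad = V if pad_index is None else pad_index
    unk = V + 1 if unk_index is None else unk_index
    instances: list[TriggerInstance] = []
    for doc_id, sent_index, forms, labels in labeled_sentences:
        kept = [
            (i, form, None if labels is None else labels[i])
            for i, form in enumerate(forms)
            if form.lower() not in stopwords
        ]
        ids = [vocab_index.get(form.lower(), unk) for _, form, _ in kept]
        for pos, (tok_i, _form, gold) in enumerate(kept):
            window = [
                ids[pos + j] if 0 <= pos + j < len(ids) else pad
                for j in range(-k, k + 1)
            ]
            instances.append(
                TriggerInstance(doc_id, sent_index, tok_i, tuple(window), gold)
            )
    return instances


def lookup_concat(instance: TriggerInstance | Sequence[int], W: np.ndarray) -> np.ndarray:
    """Concatenate the window's embedding rows end to end."""
    ids = instance.window_ids if isinstance(instance, TriggerInstance) else tuple(instance)
    ids_arr = np.asarray(ids, dtype=np.int64)
    if ids_arr.min(initial=0) < 0 or ids_arr.max(initial=0) >= W.shape[0]:
        raise IndexError("window index out of range of the lookup table")
    return W[ids_arr].reshape(-1)


# ---------------------------------------------------------------------------
# forward / backward


def _forward_pass(
    params: ModelParams,
    X: np.ndarray,
    mode: str,
    rng: np.random.Generator | None,
    dropout: float,
):
    """Returns (probs, hidden activations, dropout masks, logits)."""
    if mode not in ("train", "infer"):
        raise ValueError(f"unknown mode {mode!r}")
    train = mode == "train" and dropout > 0
    if train and rng is None:
        raise ValueError("train mode with dropout needs an rng")
    h = X
    acts = [h]
    masks: list[np.ndarray | None] = []
    for Wl, bl in params.hidden:
        z = h @ Wl + bl
        a = np.maximum(z, 0.0)
        if train:
            mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
            a = a * mask
        else:
            mask = None
        masks.append(mask)
        acts.append(a)
        h = a
    Wo, bo = params.out
    logits = h @ Wo + bo
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    return probs, acts, masks, logits


def forward(
    params: ModelParams,
    x: np.ndarray,
    mode: str = "infer",
    dropout_rng: np.random.Generator | None = None,
    dropout: float = 0.5,
) -> np.ndarray:
    """Class probability vector(s) for feature vector(s) ``x``.

    In train mode each hidden activation is dropped independently with the
    given probability and survivors are scaled by 1/(1-dropout) (inverted
    dropout); inference applies no dropout and is deterministic.
    """
    X = np.atleast_2d(x)
    probs, *_ = _forward_pass(params, X, mode, dropout_rng, dropout)
    return probs[0] if x.ndim == 1 else probs


def loss_and_gradients(
    params: ModelParams,
    batch_ids: np.ndarray,
    batch_y: np.ndarray,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Mean cross-entropy over the batch and exact gradients for the sampled
    dropout mask.

    Returns ``(loss, grad_W, grad_hidden, grad_out)``; ``grad_W`` is None in
    static mode (embedding frozen), otherwise a full dense gradient with the
    PAD row forced to zero.
    """
    if batch_ids.shape[0] == 0:
        raise ValueError("empty batch")
    B, width = batch_ids.shape
    X = params.W[batch_ids.reshape(-1)].reshape(B, width * params.size)
    mode = "train" if dropout > 0 else "infer"
    probs, acts, masks, _ = _forward_pass(params, X, mode, rng, dropout)
    eps = 1e-300
    loss = float(-np.mean(np.log(np.maximum(probs[np.arange(B), batch_y], eps))))

    d_logits = probs.copy()
    d_logits[np.arange(B), batch_y] -= 1.0
    d_logits /= B
    Wo, _bo = params.out
    hL = acts[-1]
    g_out = (hL.T @ d_logits, d_logits.sum(axis=0))
    dh = d_logits @ Wo.T
    g_hidden: list[tuple[np.ndarray, np.ndarray]] = [None] * len(params.hidden)  # type: ignore[list-item]
    for l in range(len(params.hidden) - 1, -1, -1):
        a = acts[l + 1]
        if masks[l] is not None:
            dh = dh * masks[l]
        # a > 0 marks active ReLU units (mask scaling never flips the sign)
        dz = dh * (a > 0)
        g_hidden[l] = (acts[l].T @ dz, dz.sum(axis=0))
        dh = dz @ params.hidden[l][0].T

    grad_W = None
    if params.trainable_embedding:
        dX = dh.reshape(B * width, params.size)
        grad_W = np.zeros_like(params.W)
        np.add.at(grad_W, batch_ids.reshape(-1), dX)
        grad_W[params.pad_index] = 0.0
    return loss, grad_W, g_hidden, g_out


# ---------------------------------------------------------------------------
# AdaDelta


def adadelta_update(
    grad: np.ndarray, eg2: np.ndarray, edx2: np.ndarray, rho: float = 0.95, eps: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One AdaDelta step: returns (delta, new E[g^2], new E[dx^2]).

    E[g2] <- rho E[g2] + (1-rho) g^2
    dx    =  -sqrt(E[dx2]+eps)/sqrt(E[g2]+eps) * g
    E[dx2]<- rho E[dx2] + (1-rho) dx^2
    """
    eg2 = rho * eg2 + (1.0 - rho) * grad**2
    delta = -np.sqrt(edx2 + eps) / np.sqrt(eg2 + eps) * grad
    edx2 = rho * edx2 + (1.0 - rho) * delta**2
    return delta, eg2, edx2


class AdaDeltaState:
    """Per-parameter running averages for a list of arrays."""

    def __init__(self, arrays: Sequence[np.ndarray], rho: float = 0.95, eps: float = 1e-6):
        self.rho = rho
        self.eps = eps
        self.eg2 = [np.zeros_like(a) for a in arrays]
        self.edx2 = [np.zeros_like(a) for a in arrays]

    def step(self, arrays: Sequence[np.ndarray], grads: Sequence[np.ndarray | None]) -> None:
        for i, (a, g) in enumerate(zip(arrays, grads)):
            if g is None:
                continue
            delta, self.eg2[i], self.edx2[i] = adadelta_update(
                g, self.eg2[i], self.edx2[i], self.rho, self.eps
            )
            a += delta


# ---------------------------------------------------------------------------
# training


def init_params(
    emb: EmbeddingMatrix,
    classes: Sequence[str],
    config: TrainConfig,
    rng: np.random.Generator,
) -> ModelParams:
    """Assemble the lookup table (embedding + PAD + UNK rows) and
    Glorot-initialised hidden/output layers."""
    V, size = emb.vectors.shape
    W = np.vstack([emb.vectors, np.zeros((1, size)), emb.vectors.mean(axis=0, keepdims=True)])
    dims = [(2 * config.k + 1) * size] + [config.hidden_size] * config.layers
    hidden = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        hidden.append((rng.uniform(-bound, bound, (fan_in, fan_out)), np.zeros(fan_out)))
    n_cls = len(classes)
    bound = np.sqrt(6.0 / (dims[-1] + n_cls))
    out = (rng.uniform(-bound, bound, (dims[-1], n_cls)), np.zeros(n_cls))
    return ModelParams(
        W=W,
        vocab_index=dict(emb.vocab.index),
        pad_index=V,
        unk_index=V + 1,
        hidden=hidden,
        out=out,
        classes=list(classes),
        k=config.k,
        trainable_embedding=not config.static,
    )


@dataclass
class FitResult:
    params: ModelParams
    log: list[dict]
    best_epoch: int
    significant: list[str] = field(default_factory=list)


def _param_arrays(params: ModelParams) -> list[np.ndarray]:
    arrs = [params.W]
    for w, b in params.hidden:
        arrs.extend([w, b])
    arrs.extend(params.out)
    return arrs


def _grad_arrays(grad_W, g_hidden, g_out) -> list[np.ndarray | None]:
    arrs: list[np.ndarray | None] = [grad_W]
    for gw, gb in g_hidden:
        arrs.extend([gw, gb])
    arrs.extend(g_out)
    return arrs


def _class_order(instances: Sequence[TriggerInstance]) -> list[str]:
    seen = sorted({i.gold for i in instances if i.gold is not None and i.gold != NONE_LABEL})
    return [NONE_LABEL] + seen


def _eval_micro(
    params: ModelParams, instances: Sequence[TriggerInstance], significant: Sequence[str]
) -> float:
    ids = np.asarray([i.window_ids for i in instances], dtype=np.int64)
    gold = [i.gold for i in instances]
    pred_idx = []
    for lo in range(0, len(instances), 4096):
        X = params.W[ids[lo : lo + 4096].reshape(-1)].reshape(
            min(4096, len(instances) - lo), -1
        )
        probs, *_ = _forward_pass(params, X, "infer", None, 0.0)
        pred_idx.extend(np.argmax(probs, axis=1).tolist())
    pred = [params.classes[i] for i in pred_idx]
    report = make_report(gold, pred, significant=significant)
    return report.micro_f1


def fit(
    train_instances: Sequence[TriggerInstance],
    dev_instances: Sequence[TriggerInstance],
    emb: EmbeddingMatrix,
    config: TrainConfig,
    classes: Sequence[str] | None = None,
    significant: Sequence[str] | None = None,
) -> FitResult:
    """Train with seeded shuffling, AdaDelta and early stopping on dev
    micro-F1 over the significant classes; returns the best-dev parameters
    and a per-epoch log of training loss and dev score."""
    if not train_instances:
        raise ValueError("no training instances")
    if classes is None:
        classes = _class_order(train_instances)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes (incl. NONE)")
    if significant is None:
        counts: dict[str, int] = {}
        for inst in list(train_instances) + list(dev_instances):
            if inst.gold is not None and inst.gold != NONE_LABEL:
                counts[inst.gold] = counts.get(inst.gold, 0) + 1
        significant = significant_classes(counts, config.significance_threshold)
        if not significant:
            significant = [c for c in classes if c != NONE_LABEL]

    rng = np.random.default_rng(config.seed)
    params = init_params(emb, classes, config, rng)
    cls_index = {c: i for i, c in enumerate(classes)}
    ids = np.asarray([i.window_ids for i in train_instances], dtype=np.int64)
    y = np.asarray([cls_index[i.gold] for i in train_instances], dtype=np.int64)

    state = AdaDeltaState(_param_arrays(params), config.rho, config.eps)
    best = params.copy()
    best_score = -np.inf
    best_epoch = 0
    log: list[dict] = []
    n = ids.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        loss_sum = 0.0
        for lo in range(0, n, config.batch):
            sel = order[lo : lo + config.batch]
            loss, gW, gh, go = loss_and_gradients(
                params, ids[sel], y[sel], dropout=config.dropout, rng=rng
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            loss_sum += loss * sel.size
            state.step(_param_arrays(params), _grad_arrays(gW, gh, go))
            params.W[params.pad_index] = 0.0  # PAD stays null
        train_loss = loss_sum / n
        dev_score = (
            _eval_micro(params, dev_instances, significant) if dev_instances else -train_loss
        )
        log.append({"epoch": epoch, "train_loss": train_loss, "dev_micro_f1": dev_score})
        if dev_score > best_score:
            best_score = dev_score
            best_epoch = epoch
            best = params.copy()
        if epoch - best_epoch >= config.patience:
            break
    return FitResult(params=best, log=log, best_epoch=best_epoch, significant=list(significant))


def predict(
    params: ModelParams,
    sentences: Iterable[tuple[str, int, Sequence[str]]],
    k: int | None = None,
    stopwords: frozenset[str] = STOPWORDS,
) -> list[list[str]]:
    """Per-token labels for (doc_id, sent_index, forms) sentences.

    Stop-word tokens get NONE without consulting the model; every other
    token gets the argmax class (ties resolved toward the earlier class in
    the declared order).
    """
    k = params.k if k is None else k
    sents = list(sentences)
    instances = build_instances(
        ((d, s, forms, None) for d, s, forms in sents),
        params.vocab_index,
        k,
        stopwords,
        pad_index=params.pad_index,
        unk_index=params.unk_index,
    )
    out = [[NONE_LABEL] * len(forms) for _, _, forms in sents]
    sent_pos = {(d, s): i for i, (d, s, _) in enumerate(sents)}
    if instances:
        ids = np.asarray([i.window_ids for i in instances], dtype=np.int64)
        for lo in range(0, len(instances), 4096):
            chunk = ids[lo : lo + 4096]
            X = params.W[chunk.reshape(-1)].reshape(chunk.shape[0], -1)
            probs, *_ = _forward_pass(params, X, "infer", None, 0.0)
            for inst, pi in zip(instances[lo : lo + 4096], np.argmax(probs, axis=1)):
                out[sent_pos[(inst.doc_id, inst.sent_index)]][inst.token_index] = params.classes[
                    int(pi)
                ]
    return out


# ---------------------------------------------------------------------------
# serialization


def save_model(params: ModelParams, path: str) -> None:
    """Single-archive serialization: all matrices plus JSON metadata."""
    import json

    arrays = {"W": params.W, "out_w": params.out[0], "out_b": params.out[1]}
    for i, (w, b) in enumerate(params.hidden):
        arrays[f"hidden_w_{i}"] = w
        arrays[f"hidden_b_{i}"] = b
    meta = {
        "classes": params.classes,
        "vocab": sorted(params.vocab_index, key=params.vocab_index.get),
        "pad_index": params.pad_index,
        "unk_index": params.unk_index,
        "k": params.k,
        "n_hidden": len(params.hidden),
        "trainable_embedding": params.trainable_embedding,
    }
    arrays["meta_json"] = np.asarray(json.dumps(meta))
    np.savez(path, **arrays)


def load_model(path: str) -> ModelParams:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        hidden = [
            (data[f"hidden_w_{i}"], data[f"hidden_b_{i}"]) for i in range(meta["n_hidden"])
        ]
        return ModelParams(
            W=data["W"],
            vocab_index={w: i for i, w in enumerate(meta["vocab"])},
            pad_index=meta["pad_index"],
            unk_index=meta["unk_index"],
            hidden=hidden,
            out=(data["out_w"], data["out_b"]),
            classes=meta["classes"],
            k=meta["k"],
            trainable_embedding=meta["trainable_embedding"],
        )
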