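"""End-to-end experiment plumbing: corpus -> contexts -> embeddings ->
classifier -> scores.

These helpers wire the individual stages together for the synthetic
benchmark and for the CLI: choose an embedding flavour (dependency-context,
bag-of-words, or randomly initialised with no pre-training), train the
window classifier in static or non-static mode, and score the test and
held-out-trigger splits at token level over the significant classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import FitResult, TrainConfig, build_instances, fit, predict
from .contexts import ExtractionConfig, iter_pairs
from .metrics import EvalReport, make_report, significant_classes
from .sgns import EmbeddingMatrix, SGNSConfig, Vocabulary, build_vocab, train_sgns
from .standoff import NONE_LABEL
from .stopwords import STOPWORDS
from .synth import SynthCorpus

__all__ = [
    "labeled_sentences",
    "corpus_embeddings",
    "random_embeddings",
    "ExperimentResult",
    "run_trigger_experiment",
]


def labeled_sentences(
    corpus: SynthCorpus, split: str
) -> list[tuple[str, int, list[str], list[str]]]:
    """(doc_id, sent_index, forms, gold labels) for every sentence of a split."""
    out = []
    for sdoc in corpus.docs_in(split):
        for si, (parse, labels) in enumerate(zip(sdoc.parses, sdoc.labels)):
            out.append((sdoc.doc.doc_id, si, parse.forms, list(labels)))
    return out


def corpus_embeddings(
    corpus: SynthCorpus,
    kind: str = "dependency",
    sgns_config: SGNSConfig | None = None,
    bow_window: int = 5,
) -> EmbeddingMatrix:
    """Pre-train embeddings on the corpus's unlabeled sentences.

    ``kind`` selects the context definition: "dependency" (syntactic) or
    "bow" (linear window of ``bow_window``).
    """
    if sgns_config is None:
        sgns_config = SGNSConfig()
    mode = "dependency" if kind == "dependency" else "bow"
    cfg = ExtractionConfig(mode=mode, window=bow_window)
    pairs = list(iter_pairs(corpus.unlabeled, cfg))
    result = train_sgns(pairs, sgns_config)
    return result.word


def random_embeddings(vocab: Vocabulary, size: int, seed: int) -> EmbeddingMatrix:
    """The no-pre-training ablation: same vocabulary, random vectors drawn
    like the SGNS initialisation."""
    rng = np.random.default_rng(seed)
    vectors = (rng.random((len(vocab), size)) - 0.5) / size
    return EmbeddingMatrix(vocab, vectors)


@dataclass
class ExperimentResult:
    fit: FitResult
    test_report: EvalReport
    heldout_report: EvalReport | None
    significant: list[str]

    @property
    def test_micro_f1(self) -> float:
        return self.test_report.micro_f1

    @property
    def heldout_micro_f1(self) -> float:
        return self.heldout_report.micro_f1 if self.heldout_report else float("nan")

    @property
    def dev_micro_f1(self) -> float:
        return max(rec["dev_micro_f1"] for rec in self.fit.log)


def _score_split(
    corpus: SynthCorpus, split: str, params, significant: list[str]
) -> EvalReport:
    sents = labeled_sentences(corpus, split)
    pred = predict(params, [(d, s, f) for d, s, f, _ in sents])
    gold_flat = [g for _, _, _, labels in sents for g in labels]
    pred_flat = [p for labels in pred for p in labels]
    return make_report(gold_flat, pred_flat, significant=significant)


def run_trigger_experiment(
    corpus: SynthCorpus,
    emb: EmbeddingMatrix,
    train_config: TrainConfig,
    score_heldout: bool = True,
) -> ExperimentResult:
    """Train on the corpus's train split (early stopping on dev), score on
    test and optionally on the held-out-trigger document set.

    The significant-class set is fixed once from the gold trigger counts of
    the main labeled corpus (threshold from the train config) and used for
    every aggregate.
    """
    counts = corpus.class_counts(("train", "dev", "test"))
    significant = significant_classes(counts, train_config.significance_threshold)
    k = train_config.k
    train_inst = build_instances(
        labeled_sentences(corpus, "train"), emb.vocab.index, k, STOPWORDS
    )
    dev_inst = build_instances(labeled_sentences(corpus, "dev"), emb.vocab.index, k, STOPWORDS)
    result = fit(train_inst, dev_inst, emb, train_config, significant=significant)
    test_report = _score_split(corpus, "test", result.params, significant)
    heldout_report = (
        _score_split(corpus, "heldout", result.params, significant) if score_heldout else None
    )
    return ExperimentResult(
        fit=result,
        test_report=test_report,
        heldout_report=heldout_report,
        significant=significant,
    )
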