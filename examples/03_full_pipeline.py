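"""The full trigger-detection experiment on a small synthetic benchmark.

Corpus generation -> dependency-context extraction -> SGNS pre-training ->
window classifier with fine-tuned (non-static) embeddings -> token-level
scoring over the significant classes, including the held-out-trigger
documents whose trigger words were never seen in labeled training data.
Run (~1-2 min):

    python examples/03_full_pipeline.py
"""

from deptrig.classifier import TrainConfig
from deptrig.metrics import report_tsv
from deptrig.pipeline import corpus_embeddings, run_trigger_experiment
from deptrig.sgns import SGNSConfig
from deptrig.synth import SynthConfig, generate_corpus

cfg = SynthConfig(seed=2)  # default benchmark sizes
corpus = generate_corpus(cfg)
print(
    f"corpus: {len(corpus.unlabeled)} unlabeled sentences, "
    f"{len(corpus.docs_in('train'))}/{len(corpus.docs_in('dev'))}/"
    f"{len(corpus.docs_in('test'))} train/dev/test docs, "
    f"{len(corpus.docs_in('heldout'))} held-out docs"
)

emb = corpus_embeddings(corpus, "dependency", SGNSConfig(seed=2))
print(f"pre-trained embeddings: {len(emb.vocab)} words x {emb.size}")

result = run_trigger_experiment(corpus, emb, TrainConfig(seed=2))
print(f"\nearly stopping chose epoch {result.fit.best_epoch}")
print(f"significant classes ({len(result.significant)}): {result.significant}")

print(f"\ntest micro-F1:     {result.test_micro_f1:6.2f}")
print(f"test macro-F1:     {result.test_report.macro_f1:6.2f}")
print(f"held-out micro-F1: {result.heldout_micro_f1:6.2f}")

print("\nper-class test report:")
print(report_tsv(result.test_report))
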