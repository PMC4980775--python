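"""Pre-train dependency-based embeddings on a synthetic parsed corpus and
inspect what they learned.

Generates an unlabeled parsed corpus, extracts dependency contexts, trains
skip-gram-with-negative-sampling embeddings, and queries nearest
neighbours: trigger words of the same class share syntactic frames in the
generator, so they should end up close in embedding space even though they
never co-occur in a sentence.  Run (~30 s):

    python examples/02_train_embeddings.py
"""

from deptrig.contexts import ExtractionConfig, iter_pairs
from deptrig.sgns import SGNSConfig, most_similar, train_sgns
from deptrig.synth import SynthConfig, generate_corpus

cfg = SynthConfig(n_unlabeled_sentences=2000, seed=3)
corpus = generate_corpus(cfg)

pairs = list(iter_pairs(corpus.unlabeled, ExtractionConfig(mode="dependency")))
print(f"{len(pairs)} (word, context) pairs from {len(corpus.unlabeled)} sentences")

result = train_sgns(
    pairs,
    SGNSConfig(size=50, epochs=15, min_count_word=3, min_count_context=3, seed=3),
)
for epoch, loss in enumerate(result.epoch_loss, start=1):
    print(f"epoch {epoch:2d}: mean pair loss {loss:.4f}")

emb = result.word
print(f"\nembedding matrix: {len(emb.vocab)} words x {emb.size} dimensions")

# pick two trigger classes and show neighbours of one trigger word each
for cls in list(cfg.classes)[:2]:
    words = corpus.lexicon.class_triggers[cls]
    query = next(w for w in words if w.lower() in emb.vocab.index)
    same_class = {w.lower() for w in words}
    print(f"\nclass {cls}: trigger words {words}")
    print(f"nearest neighbours of {query!r}:")
    for word, cosine in most_similar(emb, query.lower(), k=5):
        marker = "  <- same class" if word in same_class else ""
        print(f"  {word:<16} cos={cosine:+.3f}{marker}")
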