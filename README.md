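# deptrig

Biomedical event trigger detection with dependency-based word embeddings.

An event trigger is the word in a sentence that signals a biomedical event
— "inhibited" signalling Regulation, "angiogenesis" signalling
Blood_vessel_development. `deptrig` detects and classifies triggers at the
token level, following a three-stage recipe:

1. **Dependency contexts.** From dependency-parsed text (CoNLL-X, Gdep
   style), every edge `head --REL--> dependent` yields two (word, context)
   pairs: `dependent -> head/REL-1` and `head -> dependent/REL` (the
   word2vecf convention). Unlike linear bag-of-words windows, these
   contexts capture *functional* similarity: words substitutable in the
   same grammatical slot — such as trigger verbs of the same event class —
   end up close in embedding space even if they never co-occur.
2. **Skip-gram with negative sampling** pre-trains embeddings on the pair
   stream from a large unlabeled parsed corpus.
3. **A window classifier** — concatenated embedding lookups of the 2k+1
   words around each token (stop words removed), a stack of ReLU layers
   with dropout, and a softmax over `NONE` + the 19 MLEE trigger classes —
   trained with AdaDelta, with the embedding matrix either frozen
   ("static") or fine-tuned ("non-static").

Scoring uses the MLEE conventions: per-class P/R/F1 as percentages,
aggregated over the *significant* classes (≥ 10 gold instances) with both
macro-F1 (mean of per-class F1) and a summed-ratio micro-F1
(Σ2PR / Σ(P+R) over classes). See [docs/methods.md](docs/methods.md) for
the full model and the design rationale.

The package also ships IO for BioNLP standoff annotations and CoNLL-X
parses (with offset-preserving sentence splitting and tokenization), and a
seeded synthetic benchmark generator, so the entire pipeline runs and is
tested end to end without any external data.

## A worked example

Dependency vs linear contexts for one sentence
(`python examples/01_extract_contexts.py`):

```
sentence: Thalidomide inhibited the formation of capillary tubes .

dependency contexts (one line per pair):
  thalidomide  -> inhibited/SUB-1
  inhibited    -> thalidomide/SUB
  the          -> formation/NMOD-1
  formation    -> the/NMOD
  formation    -> inhibited/OBJ-1
  inhibited    -> formation/OBJ
  ...
```

`inhibited` keeps `thalidomide/SUB` and `formation/OBJ` as contexts no
matter how many words separate them, while a linear window dilutes them
with `the`, `of`, …

The full pipeline on the synthetic benchmark
(`python examples/03_full_pipeline.py`, ~1 min):

```
corpus: 4000 unlabeled sentences, 48/16/16 train/dev/test docs, 20 held-out docs
pre-trained embeddings: 282 words x 200

test micro-F1:      95.08
test macro-F1:      61.67
held-out micro-F1:  94.80
```

The held-out documents contain only trigger words that never occur in the
labeled training data — they are classified correctly only because the
pre-trained dependency embeddings place them next to their seen same-class
counterparts. With bag-of-words embeddings the same number collapses (see
below), which is the central claim of the method.

## Command line

Every stage is a subcommand; each writes its effective configuration next
to its outputs for bit-for-bit reproducibility:

```bash
deptrig synth --out corpus/ --seed 1
deptrig extract-contexts corpus/unlabeled.conllx --out pairs.txt
deptrig train-embeddings pairs.txt --out emb.txt --min-count 1 --min-count-context 1
deptrig train --corpus corpus/ --embeddings emb.txt --out model/
deptrig evaluate --corpus corpus/ --model model/model.npz --out eval/ --split test
```

## Reproduction

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
(~8 min, one CPU) recomputes the headline quantities: the recovery of the
published MLEE benchmark aggregates from their printed precision/recall,
the synthetic-benchmark micro-F1 for dependency / bag-of-words / random
embeddings and static / non-static training (5 seeds each), the
significance-filter class selection, and the closed-form AdaDelta first
step. At seed 1: dependency non-static mean test micro-F1 94.19, random
ablation 67.84, dependency held-out 94.31 vs bag-of-words 7.59.

The same guarantees run as tests in `tests/test_acceptance.py`.

## Layout

```
src/deptrig/
  standoff.py    BioNLP standoff IO, sentence split, tokenize, alignment
  conllx.py      CoNLL-X reader/writer with tree repair
  contexts.py    dependency and bag-of-words (word, context) extraction
  sgns.py        skip-gram negative-sampling training + similarity queries
  classifier.py  window MLP, dropout, AdaDelta, early stopping
  metrics.py     per-class P/R/F1, significance filter, macro/micro
  synth.py       seeded synthetic benchmark generator
  pipeline.py    corpus -> embeddings -> classifier -> reports
  corpus_io.py   on-disk corpus layout
  cli.py         the subcommands above
```
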