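"""On-disk corpus layout: standoff text/annotation pairs, CoNLL-X parses
and a split manifest.

Layout written and read by the CLI (and by the synthetic generator's
``write_corpus``)::

    <dir>/<doc_id>.txt      document text
    <dir>/<doc_id>.a2       trigger T-lines (standoff)
    <dir>/<doc_id>.conllx   dependency parses, one block per sentence
    <dir>/manifest.tsv      doc_id <TAB> split
    <dir>/unlabeled.conllx  parsed embedding-training corpus (optional)

Parse files carry no character offsets, so loading re-anchors every token
in the text by greedy left-to-right matching before triggers are projected
onto tokens.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .conllx import ParsedSentence, read_conllx, write_conllx
from .standoff import (
    StandoffDocument,
    align_triggers_to_tokens,
    assign_offsets,
    read_standoff,
    write_standoff,
)
from .synth import SynthCorpus, SynthDocument

__all__ = ["LoadedDocument", "write_corpus", "load_corpus_dir", "load_unlabeled"]


@dataclass
class LoadedDocument:
    doc: StandoffDocument
    parses: list[ParsedSentence]
    labels: list[list[str]]
    split: str


def write_corpus(corpus: SynthCorpus, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    manifest = []
    for sdoc in corpus.documents:
        doc_id = sdoc.doc.doc_id
        with open(os.path.join(outdir, f"{doc_id}.txt"), "w") as fh:
            fh.write(sdoc.doc.text)
        with open(os.path.join(outdir, f"{doc_id}.a2"), "w") as fh:
            fh.write(write_standoff(sdoc.doc))
        with open(os.path.join(outdir, f"{doc_id}.conllx"), "w") as fh:
            fh.write(write_conllx(sdoc.parses))
        manifest.append(f"{doc_id}\t{sdoc.split}")
    with open(os.path.join(outdir, "manifest.tsv"), "w") as fh:
        fh.write("\n".join(manifest) + "\n")
    with open(os.path.join(outdir, "unlabeled.conllx"), "w") as fh:
        fh.write(write_conllx(corpus.unlabeled))


def load_corpus_dir(
    path: str, entity_classes: frozenset[str] = frozenset()
) -> list[LoadedDocument]:
    """Read every manifest document: text, triggers, parses, gold labels."""
    manifest_path = os.path.join(path, "manifest.tsv")
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            entries = [ln.split("\t") for ln in fh.read().splitlines() if ln.strip()]
    else:
        entries = [
            (fn[:-4], "test")
            for fn in sorted(os.listdir(path))
            if fn.endswith(".txt")
        ]
    docs = []
    for doc_id, split in entries:
        with open(os.path.join(path, f"{doc_id}.txt")) as fh:
            text = fh.read()
        ann_path = os.path.join(path, f"{doc_id}.a2")
        ann = ""
        if os.path.exists(ann_path):
            with open(ann_path) as fh:
                ann = fh.read()
        doc = read_standoff(text, ann, doc_id, entity_classes=entity_classes)
        with open(os.path.join(path, f"{doc_id}.conllx")) as fh:
            parses = read_conllx(fh.read())
        assign_offsets(text, parses)
        labels, _dropped = align_triggers_to_tokens(doc, parses)
        docs.append(LoadedDocument(doc=doc, parses=parses, labels=labels, split=split))
    return docs


def load_unlabeled(path: str) -> list[ParsedSentence]:
    with open(path) as fh:
        return read_conllx(fh.read())
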