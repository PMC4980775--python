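"""Seeded synthetic corpora for exercising the full trigger-detection
pipeline without any external data.

The generator emulates the three inputs the method consumes:

1. an *unlabeled parsed corpus* (stands in for dependency-parsed abstracts)
   used to pre-train embeddings,
2. *labeled standoff documents* (text + trigger annotations with character
   offsets, plus gold parses) with class counts following a configurable
   profile (by default proportional to the MLEE trigger-class counts, so
   rare classes exist and exercise the significance filter), and
3. a document-disjoint train/dev/test split, plus an extra *held-out* test
   document set whose trigger words never occur in the labeled training
   data but do occur in the unlabeled corpus — the scenario in which
   pre-trained embeddings are the only route to the right class.

Structure of the synthetic language: each trigger class owns a small
lexicon of invented "verbs" and a small lexicon of class-linked "nouns".
With probability ``context_signal`` a trigger occurs in its
class-characteristic syntactic frame

    Entity  TRIGGER  [adverb]  the  CLASS-NOUN  of  Entity .

with Gdep-style relations (SUB, OBJ, NMOD, PMOD, DEP) on the edges, so that
same-class trigger words share dependency-context distributions while never
co-occurring linearly; otherwise the trigger appears in a scrambled,
uninformative frame.  Non-trigger sentences use a separate lexicon of
generic verbs and distractor nouns.  Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .conllx import ParsedSentence, Token
from .mlee import TRIGGER_CLASS_COUNTS
from .standoff import NONE_LABEL, StandoffDocument, TriggerAnnotation

__all__ = ["SynthConfig", "SynthLexicon", "SynthDocument", "SynthCorpus",
           "gen_unlabeled_parsed", "gen_labeled_standoff", "generate_corpus"]

_SYLLABLES = [
    c + v for c in "bdfgklmnprstvz" for v in ("a", "e", "i", "o", "u")
]
_VERB_SUFFIXES = ["ates", "izes", "ifies", "ures"]


def _default_profile() -> dict[str, int]:
    return dict(TRIGGER_CLASS_COUNTS)


@dataclass
class SynthConfig:
    class_profile: dict[str, int] = field(default_factory=_default_profile)
    triggers_per_class: int = 4
    heldout_per_class: int = 1
    nouns_per_class: int = 3
    entity_lexicon_size: int = 40
    distractor_vocab_size: int = 120
    n_unlabeled_sentences: int = 4000
    n_labeled_documents: int = 80
    n_triggers: int = 600
    n_heldout_documents: int = 20
    context_signal: float = 0.9
    none_sentence_rate: float = 0.2
    adverb_rate: float = 0.3
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.context_signal <= 1.0:
            raise ValueError("context_signal must be a probability")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("train/dev/test fractions must sum to 1")
        if self.heldout_per_class >= self.triggers_per_class:
            raise ValueError("need at least one non-held-out trigger word per class")

    @property
    def classes(self) -> list[str]:
        return list(self.class_profile)


@dataclass
class SynthLexicon:
    entities: list[str]
    class_triggers: dict[str, list[str]]  # all trigger words per class
    class_heldout: dict[str, list[str]]  # the held-out suffix of the above
    class_nouns: dict[str, list[str]]
    distractors: list[str]
    none_verbs: list[str]
    adverbs: list[str]

    def seen_triggers(self, cls: str) -> list[str]:
        held = set(self.class_heldout[cls])
        return [w for w in self.class_triggers[cls] if w not in held]


@dataclass
class SynthDocument:
    doc: StandoffDocument
    parses: list[ParsedSentence]
    labels: list[list[str]]
    split: str  # train | dev | test | heldout


@dataclass
class SynthCorpus:
    config: SynthConfig
    lexicon: SynthLexicon
    unlabeled: list[ParsedSentence]
    documents: list[SynthDocument]

    def docs_in(self, split: str) -> list[SynthDocument]:
        return [d for d in self.documents if d.split == split]

    def class_counts(self, splits: Iterable[str] = ("train", "dev", "test")) -> dict[str, int]:
        wanted = set(splits)
        counts: dict[str, int] = {c: 0 for c in self.config.classes}
        for d in self.documents:
            if d.split in wanted:
                for t in d.doc.triggers:
                    counts[t.cls] = counts.get(t.cls, 0) + 1
        return counts


def _make_words(
    rng: np.random.Generator,
    n: int,
    used: set[str],
    n_syll: int = 3,
    suffix: str = "",
    capital: bool = False,
) -> list[str]:
    words = []
    while len(words) < n:
        w = "".join(rng.choice(_SYLLABLES) for _ in range(n_syll)) + suffix
        if capital:
            w = w.capitalize()
        if w.lower() in used:
            continue
        used.add(w.lower())
        words.append(w)
    return words


def _build_lexicon(config: SynthConfig, rng: np.random.Generator) -> SynthLexicon:
    used: set[str] = {"the", "of"}
    entities = _make_words(rng, config.entity_lexicon_size, used, n_syll=3, capital=True)
    class_triggers: dict[str, list[str]] = {}
    class_heldout: dict[str, list[str]] = {}
    class_nouns: dict[str, list[str]] = {}
    for cls in config.classes:
        suffix = _VERB_SUFFIXES[int(rng.integers(len(_VERB_SUFFIXES)))]
        trig = _make_words(rng, config.triggers_per_class, used, n_syll=2, suffix=suffix)
        class_triggers[cls] = trig
        class_heldout[cls] = trig[config.triggers_per_class - config.heldout_per_class :]
        class_nouns[cls] = _make_words(rng, config.nouns_per_class, used, n_syll=2, suffix="ion")
    distractors = _make_words(rng, config.distractor_vocab_size, used, n_syll=3)
    none_verbs = _make_words(rng, 8, used, n_syll=2, suffix="ects")
    adverbs = _make_words(rng, 10, used, n_syll=2, suffix="ly")
    return SynthLexicon(
        entities=entities,
        class_triggers=class_triggers,
        class_heldout=class_heldout,
        class_nouns=class_nouns,
        distractors=distractors,
        none_verbs=none_verbs,
        adverbs=adverbs,
    )


def _choice(rng: np.random.Generator, seq: list[str]) -> str:
    return seq[int(rng.integers(len(seq)))]


def _sentence(tokens: list[tuple[str, int, str]]) -> ParsedSentence:
    """tokens: (form, head, rel) in order; indices are implicit."""
    return ParsedSentence(
        [Token(index=i + 1, form=f, head=h, rel=r) for i, (f, h, r) in enumerate(tokens)]
    )


def _signal_sentence(
    lex: SynthLexicon, cls: str, word: str, rng: np.random.Generator, adverb_rate: float
) -> tuple[ParsedSentence, int]:
    """Class-characteristic frame; returns the parse and the trigger's
    0-based token position."""
    e1 = _choice(rng, lex.entities)
    e2 = _choice(rng, lex.entities)
    noun = _choice(rng, lex.class_nouns[cls])
    toks: list[tuple[str, int, str]] = [(e1, 2, "SUB"), (word, 0, "ROOT")]
    trig_pos = 1
    if rng.random() < adverb_rate:
        toks.append((_choice(rng, lex.adverbs), 2, "DEP"))
    base = len(toks)
    # the(base+1) noun(base+2) of(base+3) ent(base+4) .(last)
    toks.extend(
        [
            ("the", base + 2, "NMOD"),
            (noun, 2, "OBJ"),
            ("of", base + 2, "NMOD"),
            (e2, base + 3, "PMOD"),
            (".", 2, "DEP"),
        ]
    )
    return _sentence(toks), trig_pos


def _scrambled_sentence(
    lex: SynthLexicon, word: str, rng: np.random.Generator
) -> tuple[ParsedSentence, int]:
    """The trigger word parked in a generic noun slot: no class signal."""
    e1 = _choice(rng, lex.entities)
    e2 = _choice(rng, lex.entities)
    verb = _choice(rng, lex.none_verbs)
    toks = [
        (e1, 2, "SUB"),
        (verb, 0, "ROOT"),
        ("the", 4, "NMOD"),
        (word, 2, "OBJ"),
        ("of", 4, "NMOD"),
        (e2, 5, "PMOD"),
        (".", 2, "DEP"),
    ]
    return _sentence(toks), 3


def _none_sentence(
    lex: SynthLexicon, rng: np.random.Generator, adverb_rate: float
) -> ParsedSentence:
    e1 = _choice(rng, lex.entities)
    e2 = _choice(rng, lex.entities)
    verb = _choice(rng, lex.none_verbs)
    noun = _choice(rng, lex.distractors)
    toks: list[tuple[str, int, str]] = [(e1, 2, "SUB"), (verb, 0, "ROOT")]
    if rng.random() < adverb_rate:
        toks.append((_choice(rng, lex.adverbs), 2, "DEP"))
    base = len(toks)
    toks.extend(
        [
            ("the", base + 2, "NMOD"),
            (noun, 2, "OBJ"),
            ("of", base + 2, "NMOD"),
            (e2, base + 3, "PMOD"),
            (".", 2, "DEP"),
        ]
    )
    return _sentence(toks)


def _class_probs(config: SynthConfig) -> np.ndarray:
    w = np.asarray([config.class_profile[c] for c in config.classes], dtype=np.float64)
    return w / w.sum()


def gen_unlabeled_parsed(
    config: SynthConfig, lexicon: SynthLexicon | None = None
) -> list[ParsedSentence]:
    """The embedding-training corpus: parsed sentences mixing trigger frames
    (all trigger words, held-out ones included) and generic sentences."""
    rng = np.random.default_rng(config.seed)
    lex = lexicon if lexicon is not None else _build_lexicon(config, rng)
    probs = _class_probs(config)
    classes = config.classes
    sentences = []
    for _ in range(config.n_unlabeled_sentences):
        if rng.random() < 0.75:
            cls = classes[int(rng.choice(len(classes), p=probs))]
            word = _choice(rng, lex.class_triggers[cls])
            if rng.random() < config.context_signal:
                sent, _pos = _signal_sentence(lex, cls, word, rng, config.adverb_rate)
            else:
                sent, _pos = _scrambled_sentence(lex, word, rng)
        else:
            sent = _none_sentence(lex, rng, config.adverb_rate)
        sentences.append(sent)
    return sentences


def _render_document(
    doc_id: str,
    sent_specs: list[tuple[ParsedSentence, int | None, str | None]],
) -> SynthDocument:
    """Lay sentences out as text, fixing token offsets and trigger spans.

    Tokens are space-separated except the sentence-final period, which
    attaches to the preceding word.
    """
    text_parts: list[str] = []
    offset = 0
    parses: list[ParsedSentence] = []
    labels: list[list[str]] = []
    triggers: list[TriggerAnnotation] = []
    for sent, trig_pos, cls in sent_specs:
        sent_labels = []
        for i, tok in enumerate(sent.tokens):
            if i > 0 and tok.form != ".":
                text_parts.append(" ")
                offset += 1
            tok.start = offset
            tok.end = offset + len(tok.form)
            text_parts.append(tok.form)
            offset = tok.end
            sent_labels.append(cls if (trig_pos is not None and i == trig_pos) else NONE_LABEL)
        if trig_pos is not None and cls is not None:
            trig_tok = sent.tokens[trig_pos]
            triggers.append(
                TriggerAnnotation(
                    ann_id=f"T{len(triggers) + 1}",
                    cls=cls,
                    start=trig_tok.start,
                    end=trig_tok.end,
                    surface=trig_tok.form,
                )
            )
        text_parts.append(" ")
        offset += 1
        parses.append(sent)
        labels.append(sent_labels)
    text = "".join(text_parts).rstrip()
    doc = StandoffDocument(doc_id=doc_id, text=text, triggers=triggers)
    doc.validate()
    return SynthDocument(doc=doc, parses=parses, labels=labels, split="")


def gen_labeled_standoff(
    config: SynthConfig, lexicon: SynthLexicon | None = None
) -> list[SynthDocument]:
    """Annotated documents with a document-disjoint train/dev/test split and
    an extra held-out-trigger document set."""
    # separate stream from the unlabeled corpus, but same lexicon seed
    lex_rng = np.random.default_rng(config.seed)
    lex = lexicon if lexicon is not None else _build_lexicon(config, lex_rng)
    rng = np.random.default_rng(config.seed + 1_000_003)
    probs = _class_probs(config)
    classes = config.classes

    n_main = config.n_labeled_documents
    order = rng.permutation(n_main)
    n_train = int(round(config.fractions[0] * n_main))
    n_dev = int(round(config.fractions[1] * n_main))
    split_of = {}
    for rank, doc_i in enumerate(order):
        split_of[int(doc_i)] = (
            "train" if rank < n_train else "dev" if rank < n_train + n_dev else "test"
        )

    per_doc = [config.n_triggers // n_main] * n_main
    for i in range(config.n_triggers % n_main):
        per_doc[i] += 1

    documents: list[SynthDocument] = []

    def build_doc(doc_id: str, split: str, n_trig: int) -> SynthDocument:
        specs: list[tuple[ParsedSentence, int | None, str | None]] = []
        for _ in range(n_trig):
            cls = classes[int(rng.choice(len(classes), p=probs))]
            if split == "train":
                word = _choice(rng, lex.seen_triggers(cls))
            elif split == "heldout":
                word = _choice(rng, lex.class_heldout[cls])
            else:
                word = _choice(rng, lex.class_triggers[cls])
            if rng.random() < config.context_signal:
                sent, pos = _signal_sentence(lex, cls, word, rng, config.adverb_rate)
            else:
                sent, pos = _scrambled_sentence(lex, word, rng)
            specs.append((sent, pos, cls))
        n_none = max(1, int(round(config.none_sentence_rate * n_trig)))
        for _ in range(n_none):
            specs.append((_none_sentence(lex, rng, config.adverb_rate), None, None))
        perm = rng.permutation(len(specs))
        specs = [specs[i] for i in perm]
        sdoc = _render_document(doc_id, specs)
        sdoc.split = split
        return sdoc

    for i in range(n_main):
        documents.append(build_doc(f"synth{i:04d}", split_of[i], per_doc[i]))
    per_held = max(1, config.n_triggers // max(n_main, 1))
    for j in range(config.n_heldout_documents):
        documents.append(build_doc(f"heldout{j:04d}", "heldout", per_held))
    return documents


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """The full benchmark: shared lexicon, unlabeled corpus, labeled docs."""
    rng = np.random.default_rng(config.seed)
    lex = _build_lexicon(config, rng)
    unlabeled = gen_unlabeled_parsed(config, lexicon=lex)
    documents = gen_labeled_standoff(config, lexicon=lex)
    return SynthCorpus(config=config, lexicon=lex, unlabeled=unlabeled, documents=documents)
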