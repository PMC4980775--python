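"""BioNLP shared-task standoff annotation IO plus offset-preserving
sentence splitting and tokenization.

Standoff annotation keeps the document text in a ``.txt`` file and typed
character spans in separate ``.a1``/``.a2``/``.ann`` files whose ``T`` lines
look like ``T3<TAB>Regulation 12 21<TAB>inhibited``.  Only trigger spans are
modelled here; entity ``T`` lines can be filtered out via a configurable
entity-class list and event/modifier lines (``E``, ``M``, ``*``, ...) are
ignored, since the trigger detector uses neither.

Sentence splitting and tokenization are deterministic rule-based procedures
that always preserve character offsets into the original text, so that
token-level labels can be projected back onto annotation spans.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .conllx import ParsedSentence, Token

__all__ = [
    "NONE_LABEL",
    "TriggerAnnotation",
    "StandoffDocument",
    "read_standoff",
    "write_standoff",
    "split_sentences",
    "tokenize",
    "align_triggers_to_tokens",
    "assign_offsets",
]

logger = logging.getLogger(__name__)

#: reserved label for tokens that are not part of any trigger
NONE_LABEL = "NONE"

# words (lowercased, sans final period) that never end a sentence
_ABBREVIATIONS = {
    "e", "al", "fig", "figs", "eq", "eqs", "ref", "refs", "no", "cf",
    "vs", "etc", "dr", "mr", "mrs", "st", "i.e", "e.g", "approx",
}

_OPEN_PUNCT = set("([{\"'‘“")
_CLOSE_PUNCT = set(")]}\"'’”.,;:!?")


@dataclass
class TriggerAnnotation:
    """A typed trigger span: half-open 0-based character offsets."""

    ann_id: str
    cls: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.ann_id}: empty or inverted span {self.start}..{self.end}")
        if not self.cls:
            raise ValueError(f"{self.ann_id}: empty class")


@dataclass
class StandoffDocument:
    doc_id: str
    text: str
    triggers: list[TriggerAnnotation] = field(default_factory=list)

    def validate(self) -> None:
        for trig in self.triggers:
            if not (0 <= trig.start < len(self.text)) or trig.end > len(self.text):
                raise ValueError(f"{trig.ann_id}: span outside document text")
            if self.text[trig.start : trig.end] != trig.surface:
                raise ValueError(
                    f"{trig.ann_id}: surface {trig.surface!r} does not match text "
                    f"slice {self.text[trig.start:trig.end]!r}"
                )


def read_standoff(
    text_content: str,
    ann_content: str,
    doc_id: str = "",
    entity_classes: frozenset[str] | set[str] = frozenset(),
) -> StandoffDocument:
    """Parse a ``.txt`` + annotation file pair into a :class:`StandoffDocument`.

    ``T`` lines whose class is in ``entity_classes`` are skipped (they mark
    named entities, which this pipeline does not use); every other line type
    is ignored.  Surface strings are validated against the text.
    """
    triggers: list[TriggerAnnotation] = []
    for lineno, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip() or not line.startswith("T"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
        ann_id, type_span = fields[0], fields[1]
        surface = fields[2]
        parts = type_span.split()
        if len(parts) != 3:
            raise ValueError(
                f"line {lineno}: expected 'CLASS START END' in second field, got {type_span!r}"
            )
        cls = parts[0]
        if cls in entity_classes:
            continue
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer offsets in {type_span!r}") from exc
        triggers.append(TriggerAnnotation(ann_id, cls, start, end, surface))
    doc = StandoffDocument(doc_id=doc_id, text=text_content, triggers=triggers)
    doc.validate()
    return doc


def write_standoff(doc: StandoffDocument) -> str:
    """Serialise the trigger annotations back to ``T`` lines."""
    lines = [f"{t.ann_id}\t{t.cls} {t.start} {t.end}\t{t.surface}" for t in doc.triggers]
    return "\n".join(lines) + ("\n" if lines else "")


def _is_abbreviation(text: str, period_pos: int) -> bool:
    # word immediately preceding the period
    i = period_pos
    j = i
    while j > 0 and not text[j - 1].isspace():
        j -= 1
    word = text[j:i].rstrip(".")
    if not word:
        return False
    if len(word) == 1 and word.isupper():
        return True  # initials: "E. coli", "J. Smith"
    return word.lower() in _ABBREVIATIONS


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split ``text`` into sentence spans (0-based, half-open).

    A sentence ends at ``.``, ``!`` or ``?`` followed by whitespace and an
    uppercase letter or digit, unless the preceding word is a known
    abbreviation or a single capital initial.  Spans are disjoint, ordered,
    and jointly cover all non-whitespace characters.
    """
    spans: list[tuple[int, int]] = []
    n = len(text)
    start = 0
    while start < n and text[start].isspace():
        start += 1
    if start >= n:
        return []
    for m in re.finditer(r"[.!?]+", text):
        end = m.end()
        if end >= n:
            break
        # require whitespace then an uppercase letter / digit
        k = end
        while k < n and text[k].isspace():
            k += 1
        if k == end or k >= n:
            continue
        if not (text[k].isupper() or text[k].isdigit()):
            continue
        if text[m.start()] == "." and m.end() - m.start() == 1 and _is_abbreviation(text, m.start()):
            continue
        if end > start:
            spans.append((start, end))
            start = k
    # trailing sentence
    tail_end = n
    while tail_end > start and text[tail_end - 1].isspace():
        tail_end -= 1
    if tail_end > start:
        spans.append((start, tail_end))
    return spans


def tokenize(text: str, span: tuple[int, int] | None = None) -> list[Token]:
    """Tokenize a text span into offset-carrying tokens (head/rel unset).

    Whitespace-splitting with leading/trailing punctuation detached as
    separate tokens; hyphenated words and word-internal punctuation are kept
    whole.
    """
    start, end = span if span is not None else (0, len(text))
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text[start:end]):
        s = start + m.start()
        e = start + m.end()
        # detach leading punctuation
        while s < e - 0 and text[s] in _OPEN_PUNCT and e - s > 1:
            tokens.append(Token(index=0, form=text[s], start=s, end=s + 1))
            s += 1
        # detach trailing punctuation (collect, emit after the core token)
        trail: list[Token] = []
        while e > s + 1 and text[e - 1] in _CLOSE_PUNCT:
            trail.append(Token(index=0, form=text[e - 1], start=e - 1, end=e))
            e -= 1
        tokens.append(Token(index=0, form=text[s:e], start=s, end=e))
        tokens.extend(reversed(trail))
    for i, tok in enumerate(tokens, start=1):
        tok.index = i
    return tokens


def align_triggers_to_tokens(
    doc: StandoffDocument, sentences: list[ParsedSentence]
) -> tuple[list[list[str]], list[TriggerAnnotation]]:
    """Project trigger spans onto tokens by character overlap.

    Returns per-sentence label lists (parallel to the token lists) and the
    triggers that overlapped no token (these are dropped with a warning).
    A token overlapping several triggers takes the one with the largest
    overlap, earlier trigger on ties; multi-token triggers label every
    overlapped token.
    """
    labels: list[list[str]] = []
    hit: set[int] = set()
    for sent in sentences:
        sent_labels = []
        for tok in sent:
            if tok.start < 0:
                sent_labels.append(NONE_LABEL)
                continue
            best = None
            best_ov = 0
            for ti, trig in enumerate(doc.triggers):
                ov = min(tok.end, trig.end) - max(tok.start, trig.start)
                if ov > best_ov:
                    best, best_ov = ti, ov
            if best is None:
                sent_labels.append(NONE_LABEL)
            else:
                sent_labels.append(doc.triggers[best].cls)
                hit.add(best)
        labels.append(sent_labels)
    dropped = [t for i, t in enumerate(doc.triggers) if i not in hit]
    for trig in dropped:
        logger.warning(
            "%s: trigger %s %r (%d,%d) overlaps no token; dropped",
            doc.doc_id, trig.ann_id, trig.surface, trig.start, trig.end,
        )
    return labels, dropped


def assign_offsets(text: str, sentences: list[ParsedSentence]) -> list[ParsedSentence]:
    """Recover character offsets for parsed tokens by greedy left-to-right
    search of each token form in ``text``.

    Used when a parse file (CoNLL-X carries no offsets) must be aligned with
    the standoff text it was produced from.  Tokens that cannot be located
    keep offset -1.
    """
    pos = 0
    for sent in sentences:
        for tok in sent:
            found = text.find(tok.form, pos)
            if found < 0:
                continue
            tok.start = found
            tok.end = found + len(tok.form)
            pos = tok.end
    return sentences
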