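"""(word, context) training-pair extraction for embedding training.

Two context definitions are supported:

* **dependency** contexts — one pair per side of every dependency edge.
  For an edge head *h* --L--> dependent *d*, the head sees the dependent
  through the plain relation and the dependent sees its head through the
  inverse relation, marked ``-1``::

      (h, "d/L")        (d, "h/L-1")

  e.g. the edge ``formation --NMOD--> the`` yields ``(formation, the/NMOD)``
  and ``(the, formation/NMOD-1)``.  Embeddings trained on these pairs group
  words by syntactic function (what a word *does* in sentences) rather than
  by topic, which is what trigger classification needs.

* **bow** (bag-of-words) contexts — the classic linear window: each word is
  paired with every neighbour within ``c`` positions.

Pairs are streamed to/from two-column whitespace-separated text, the input
format of word2vecf-style trainers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .conllx import ParsedSentence, Token

__all__ = [
    "ContextPair",
    "ExtractionConfig",
    "extract_dep_contexts",
    "extract_bow_contexts",
    "iter_pairs",
    "write_pairs",
    "read_pairs",
]

#: suffix marking the inverse (dependent-to-head) direction of a relation
INVERSE_SUFFIX = "-1"


@dataclass(frozen=True)
class ContextPair:
    word: str
    context: str


@dataclass
class ExtractionConfig:
    mode: str = "dependency"  # "dependency" | "bow"
    window: int = 5  # bow mode only
    lowercase: bool = True
    include_punct: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("dependency", "bow"):
            raise ValueError(f"unknown extraction mode {self.mode!r}")
        if self.mode == "bow" and self.window < 1:
            raise ValueError("bow window must be >= 1")


def _is_punct(form: str) -> bool:
    return not any(ch.isalnum() for ch in form)


def extract_dep_contexts(
    sentence: ParsedSentence, lowercase: bool = True, include_punct: bool = True
) -> list[ContextPair]:
    """Emit the two pairs of every dependency edge, ordered by dependent.

    The root's attachment to the artificial node 0 emits nothing, so an
    n-token sentence yields exactly 2(n-1) pairs (before punctuation
    filtering).
    """
    norm = (lambda s: s.lower()) if lowercase else (lambda s: s)
    pairs: list[ContextPair] = []
    for head, dep, rel in sentence.edges():
        if not include_punct and (_is_punct(head.form) or _is_punct(dep.form)):
            continue
        h, d = norm(head.form), norm(dep.form)
        pairs.append(ContextPair(d, f"{h}/{rel}{INVERSE_SUFFIX}"))
        pairs.append(ContextPair(h, f"{d}/{rel}"))
    return pairs


def extract_bow_contexts(
    tokens: Sequence[Token] | Sequence[str], c: int, lowercase: bool = True
) -> list[ContextPair]:
    """Linear-window pairs: (w_t, w_{t+j}) for j in [-c, c], j != 0."""
    if c < 1:
        raise ValueError("window size c must be >= 1")
    forms = [t.form if isinstance(t, Token) else t for t in tokens]
    if lowercase:
        forms = [f.lower() for f in forms]
    n = len(forms)
    pairs: list[ContextPair] = []
    for t in range(n):
        for j in range(-c, c + 1):
            if j == 0:
                continue
            u = t + j
            if 0 <= u < n:
                pairs.append(ContextPair(forms[t], forms[u]))
    return pairs


def iter_pairs(
    sentences: Iterable[ParsedSentence], config: ExtractionConfig
) -> Iterator[ContextPair]:
    """Stream pairs over a sentence corpus under ``config``."""
    for sent in sentences:
        if config.mode == "dependency":
            yield from extract_dep_contexts(
                sent, lowercase=config.lowercase, include_punct=config.include_punct
            )
        else:
            toks = sent.tokens
            if not config.include_punct:
                toks = [t for t in toks if not _is_punct(t.form)]
            yield from extract_bow_contexts(toks, config.window, lowercase=config.lowercase)


def write_pairs(pairs: Iterable[ContextPair]) -> str:
    return "".join(f"{p.word} {p.context}\n" for p in pairs)


def read_pairs(content: str) -> list[ContextPair]:
    pairs = []
    for lineno, line in enumerate(content.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 2 columns, got {len(parts)}")
        pairs.append(ContextPair(parts[0], parts[1]))
    return pairs
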