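"""Dependency-parsed sentences and CoNLL-X reading/writing.

The pipeline consumes the tab-separated CoNLL-X output of a dependency
parser (one token per line: ID, FORM, LEMMA, CPOSTAG, POSTAG, FEATS, HEAD,
DEPREL; sentences separated by blank lines).  Real parser output is dirty:
multi-rooted or cyclic "trees" occur, and downstream context extraction
requires an actual tree, so reading repairs such sentences by re-attaching
offending tokens to the first root with the relation ``DEP``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

__all__ = ["Token", "ParsedSentence", "read_conllx", "write_conllx", "repair_tree"]

#: relation used when re-attaching tokens during tree repair
REPAIR_REL = "DEP"


@dataclass
class Token:
    """One token of a dependency-parsed sentence.

    ``index`` is 1-based; ``head`` is the index of the governing token with
    0 denoting the artificial root.  ``start``/``end`` are character offsets
    into the source document text, or -1 when the parse carries none.
    """

    index: int
    form: str
    lemma: str = "_"
    pos: str = "_"
    head: int = 0
    rel: str = "_"
    start: int = -1
    end: int = -1


@dataclass
class ParsedSentence:
    """An ordered list of tokens forming a single-rooted dependency tree."""

    tokens: list[Token] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)

    @property
    def forms(self) -> list[str]:
        return [t.form for t in self.tokens]

    def root(self) -> Token:
        for t in self.tokens:
            if t.head == 0:
                return t
        raise ValueError("sentence has no root token")

    def edges(self) -> list[tuple[Token, Token, str]]:
        """All (head, dependent, relation) edges, excluding the root's
        attachment to the artificial node, ordered by dependent index."""
        by_index = {t.index: t for t in self.tokens}
        out = []
        for t in self.tokens:
            if t.head != 0:
                out.append((by_index[t.head], t, t.rel))
        return out


def repair_tree(sentence: ParsedSentence) -> ParsedSentence:
    """Enforce the single-root, acyclic invariants in place.

    The first token with head 0 is kept as root (if none exists, the first
    token becomes root); every other head-0 token and every token from which
    the root is unreachable is re-attached to the root with ``DEP``.
    """
    toks = sentence.tokens
    if not toks:
        return sentence
    roots = [t for t in toks if t.head == 0]
    if not roots:
        toks[0].head = 0
        toks[0].rel = "ROOT"
        root = toks[0]
    else:
        root = roots[0]
        for extra in roots[1:]:
            extra.head = root.index
            extra.rel = REPAIR_REL
    by_index = {t.index: t for t in toks}
    # break cycles: any token that cannot reach the root sits on (or hangs
    # off) a cycle; re-attach the smallest-index unreachable token and retry
    while True:
        reachable = {root.index}
        for t in toks:
            path = []
            cur = t
            while cur.index not in reachable:
                if cur.index in path:
                    break
                path.append(cur.index)
                if cur.head == 0:
                    break
                cur = by_index[cur.head]
            else:
                reachable.update(path)
        unreachable = [t for t in toks if t.index not in reachable]
        if not unreachable:
            break
        bad = min(unreachable, key=lambda t: t.index)
        bad.head = root.index
        bad.rel = REPAIR_REL
    return sentence


def _parse_block(lines: list[tuple[int, str]], ordinal: int) -> ParsedSentence:
    tokens = []
    for lineno, line in lines:
        cols = line.split("\t")
        if len(cols) < 8:
            raise ValueError(
                f"sentence {ordinal}, line {lineno}: expected >=8 tab-separated "
                f"columns, got {len(cols)}"
            )
        try:
            idx = int(cols[0])
            head = int(cols[6])
        except ValueError as exc:
            raise ValueError(
                f"sentence {ordinal}, line {lineno}: non-integer ID/HEAD"
            ) from exc
        tokens.append(
            Token(index=idx, form=cols[1], lemma=cols[2], pos=cols[4], head=head, rel=cols[7])
        )
    n = len(tokens)
    for lineno, tok in zip((ln for ln, _ in lines), tokens):
        if not (0 <= tok.head <= n):
            raise ValueError(
                f"sentence {ordinal}, line {lineno}: HEAD {tok.head} out of range 0..{n}"
            )
        if tok.head == tok.index:
            # a self-loop is a 1-cycle; clear it and let repair re-attach
            tok.head = 0
            tok.rel = REPAIR_REL
    return repair_tree(ParsedSentence(tokens))


def read_conllx(content: str) -> list[ParsedSentence]:
    """Parse CoNLL-X text into sentences, repairing tree violations."""
    sentences: list[ParsedSentence] = []
    block: list[tuple[int, str]] = []
    for lineno, raw in enumerate(content.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            if block:
                sentences.append(_parse_block(block, len(sentences) + 1))
                block = []
            continue
        if line.startswith("#"):
            continue
        block.append((lineno, line))
    if block:
        sentences.append(_parse_block(block, len(sentences) + 1))
    return sentences


def write_conllx(sentences: list[ParsedSentence]) -> str:
    """Serialise sentences in 8+2 column CoNLL-X form."""
    out = []
    for sent in sentences:
        for t in sent:
            out.append(
                "\t".join(
                    [str(t.index), t.form, t.lemma, t.pos, t.pos, "_", str(t.head), t.rel, "_", "_"]
                )
            )
        out.append("")
    return "\n".join(out) + ("\n" if out else "")
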