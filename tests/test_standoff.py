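"""Standoff annotation IO, sentence splitting, tokenization, CoNLL-X
reading and trigger-to-token alignment."""

import pytest

from deptrig.conllx import read_conllx, write_conllx
from deptrig.standoff import (
    NONE_LABEL,
    StandoffDocument,
    TriggerAnnotation,
    align_triggers_to_tokens,
    assign_offsets,
    read_standoff,
    split_sentences,
    tokenize,
    write_standoff,
)

TEXT = "Thalidomide inhibited X."


class TestReadStandoff:
    def test_single_trigger(self):
        doc = read_standoff(TEXT, "T1\tRegulation 12 21\tinhibited", "d1")
        assert len(doc.triggers) == 1
        t = doc.triggers[0]
        assert (t.cls, t.start, t.end, t.surface) == ("Regulation", 12, 21, "inhibited")

    def test_empty_annotation(self):
        assert read_standoff(TEXT, "", "d1").triggers == []

    def test_surface_mismatch_names_id(self):
        with pytest.raises(ValueError, match="T1"):
            read_standoff(TEXT, "T1\tRegulation 12 21\tinhibitedX", "d1")

    def test_entity_lines_skipped(self):
        ann = "T1\tDrug 0 11\tThalidomide\nT2\tRegulation 12 21\tinhibited"
        doc = read_standoff(TEXT, ann, "d1", entity_classes=frozenset({"Drug"}))
        assert [t.cls for t in doc.triggers] == ["Regulation"]

    def test_malformed_line_names_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            read_standoff(TEXT, "T1\tRegulation 12 21\tinhibited\nT2\tbroken", "d1")

    def test_event_lines_ignored(self):
        ann = "T1\tRegulation 12 21\tinhibited\nE1\tRegulation:T1"
        assert len(read_standoff(TEXT, ann, "d1").triggers) == 1

    def test_round_trip(self):
        ann = "T1\tRegulation 12 21\tinhibited\nT2\tDevelopment 22 23\tX"
        doc = read_standoff(TEXT, ann, "d1")
        again = read_standoff(TEXT, write_standoff(doc), "d1")
        assert [
            (t.ann_id, t.cls, t.start, t.end, t.surface) for t in again.triggers
        ] == [(t.ann_id, t.cls, t.start, t.end, t.surface) for t in doc.triggers]


class TestSplitSentences:
    def test_two_terminal_periods(self):
        assert split_sentences("A b. C d.") == [(0, 4), (5, 9)]

    def test_empty(self):
        assert split_sentences("") == []
        assert split_sentences("   ") == []

    def test_abbreviation_guard(self):
        spans = split_sentences("E. coli grows. It divides.")
        assert len(spans) == 2
        s, e = spans[0]
        assert "E. coli grows." == "E. coli grows. It divides."[s:e]

    def test_spans_cover_non_whitespace(self):
        text = "Alpha beta.  Gamma delta!  Epsilon."
        spans = split_sentences(text)
        covered = set()
        for s, e in spans:
            covered.update(range(s, e))
        for i, ch in enumerate(text):
            if not ch.isspace():
                assert i in covered
        assert spans == sorted(spans)


class TestTokenize:
    def test_offsets_and_period(self):
        toks = tokenize("inhibited X.")
        assert [t.form for t in toks] == ["inhibited", "X", "."]
        assert [(t.start, t.end) for t in toks] == [(0, 9), (10, 11), (11, 12)]

    def test_hyphenated_kept_whole(self):
        assert [t.form for t in tokenize("capillary-like")] == ["capillary-like"]

    def test_parentheses_detached(self):
        assert [t.form for t in tokenize("(VEGF)")] == ["(", "VEGF", ")"]

    def test_offset_soundness_on_generated_documents(self, small_corpus):
        for sdoc in small_corpus.documents[:6]:
            text = sdoc.doc.text
            for span in split_sentences(text):
                for tok in tokenize(text, span):
                    assert text[tok.start : tok.end] == tok.form


class TestReadConllx:
    def test_two_token_block(self):
        content = (
            "1\tThalidomide\t_\tN\tN\t_\t2\tSUB\n"
            "2\tinhibited\t_\tV\tV\t_\t0\tROOT\n"
        )
        sents = read_conllx(content)
        assert len(sents) == 1
        assert [t.form for t in sents[0]] == ["Thalidomide", "inhibited"]
        assert (sents[0].tokens[0].head, sents[0].tokens[0].rel) == (2, "SUB")

    def test_empty(self):
        assert read_conllx("") == []

    def test_multi_root_repair(self):
        content = "1\ta\t_\tN\tN\t_\t0\tROOT\n2\tb\t_\tV\tV\t_\t0\tROOT\n"
        (sent,) = read_conllx(content)
        roots = [t for t in sent if t.head == 0]
        assert len(roots) == 1 and roots[0].form == "a"
        assert sent.tokens[1].head == 1 and sent.tokens[1].rel == "DEP"

    def test_cycle_repair_reaches_root(self):
        content = (
            "1\ta\t_\tN\tN\t_\t0\tROOT\n"
            "2\tb\t_\tN\tN\t_\t3\tNMOD\n"
            "3\tc\t_\tN\tN\t_\t2\tNMOD\n"
        )
        (sent,) = read_conllx(content)
        by_index = {t.index: t for t in sent}
        for tok in sent:
            seen = set()
            cur = tok
            while cur.head != 0:
                assert cur.index not in seen
                seen.add(cur.index)
                cur = by_index[cur.head]

    def test_head_out_of_range_error(self):
        with pytest.raises(ValueError, match="sentence 1"):
            read_conllx("1\ta\t_\tN\tN\t_\t5\tSUB\n")

    def test_non_integer_head_error(self):
        with pytest.raises(ValueError, match="non-integer"):
            read_conllx("1\ta\t_\tN\tN\t_\tx\tSUB\n")

    def test_write_read_round_trip(self, small_corpus):
        parses = small_corpus.documents[0].parses
        again = read_conllx(write_conllx(parses))
        assert [[(t.form, t.head, t.rel) for t in s] for s in again] == [
            [(t.form, t.head, t.rel) for t in s] for s in parses
        ]


class TestAlignTriggers:
    def _doc_and_parse(self):
        text = "Thalidomide inhibited X."
        doc = read_standoff(text, "T1\tRegulation 12 21\tinhibited", "d")
        sents = read_conllx(
            "1\tThalidomide\t_\tN\tN\t_\t2\tSUB\n"
            "2\tinhibited\t_\tV\tV\t_\t0\tROOT\n"
            "3\tX\t_\tN\tN\t_\t2\tOBJ\n"
            "4\t.\t_\t.\t.\t_\t2\tDEP\n"
        )
        assign_offsets(text, sents)
        return doc, sents

    def test_exact_overlap(self):
        doc, sents = self._doc_and_parse()
        labels, dropped = align_triggers_to_tokens(doc, sents)
        assert labels == [["NONE", "Regulation", "NONE", "NONE"]]
        assert dropped == []

    def test_no_triggers_all_none(self):
        doc, sents = self._doc_and_parse()
        doc.triggers = []
        labels, _ = align_triggers_to_tokens(doc, sents)
        assert all(l == NONE_LABEL for sent in labels for l in sent)

    def test_multi_token_trigger_labels_every_token(self):
        text = "capillary tubes formed."
        doc = StandoffDocument("d", text, [TriggerAnnotation("T1", "Growth", 0, 15, "capillary tubes")])
        sents = read_conllx(
            "1\tcapillary\t_\tN\tN\t_\t2\tNMOD\n"
            "2\ttubes\t_\tN\tN\t_\t3\tSUB\n"
            "3\tformed\t_\tV\tV\t_\t0\tROOT\n"
            "4\t.\t_\t.\t.\t_\t3\tDEP\n"
        )
        assign_offsets(text, sents)
        labels, _ = align_triggers_to_tokens(doc, sents)
        assert labels == [["Growth", "Growth", "NONE", "NONE"]]

    def test_unanchored_trigger_dropped_and_reported(self):
        doc, sents = self._doc_and_parse()
        doc.text = doc.text + "          "
        doc.triggers.append(TriggerAnnotation("T9", "Death", 25, 26, " "))
        labels, dropped = align_triggers_to_tokens(doc, sents)
        assert [t.ann_id for t in dropped] == ["T9"]
        assert labels[0][1] == "Regulation"

    def test_labeled_tokens_always_overlap_some_trigger(self, small_corpus):
        for sdoc in small_corpus.documents[:6]:
            labels, dropped = align_triggers_to_tokens(sdoc.doc, sdoc.parses)
            assert not dropped
            for sent, sent_labels in zip(sdoc.parses, labels):
                for tok, lab in zip(sent, sent_labels):
                    if lab != NONE_LABEL:
                        assert any(
                            min(tok.end, t.end) - max(tok.start, t.start) > 0
                            for t in sdoc.doc.triggers
                        )
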