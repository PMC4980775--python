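"""Dependency-based vs bag-of-words context extraction, on one sentence.

The embedding-training signal is a stream of (word, context) pairs.  For
the bag-of-words flavour a context is simply a neighbouring word inside a
linear window.  For the dependency flavour each parse edge head --REL-->
dependent contributes two pairs: the dependent paired with "head/REL-1"
(the -1 marks the inverse direction) and the head paired with
"dependent/REL".  Run:

    python examples/01_extract_contexts.py
"""

from deptrig.conllx import read_conllx
from deptrig.contexts import extract_bow_contexts, extract_dep_contexts

# A Gdep-style CoNLL-X parse of:
#   "Thalidomide inhibited the formation of capillary tubes."
CONLLX = """\
1\tThalidomide\t_\tNN\tNN\t_\t2\tSUB
2\tinhibited\t_\tVBD\tVBD\t_\t0\tROOT
3\tthe\t_\tDT\tDT\t_\t4\tNMOD
4\tformation\t_\tNN\tNN\t_\t2\tOBJ
5\tof\t_\tIN\tIN\t_\t4\tNMOD
6\tcapillary\t_\tNN\tNN\t_\t7\tNMOD
7\ttubes\t_\tNNS\tNNS\t_\t5\tPMOD
8\t.\t_\t.\t.\t_\t2\tP
"""

(sentence,) = read_conllx(CONLLX)

print("sentence:", " ".join(sentence.forms))
print()

print("dependency contexts (one line per pair):")
for pair in extract_dep_contexts(sentence):
    print(f"  {pair.word:<12} -> {pair.context}")
print()

print("bag-of-words contexts, window 2:")
for pair in extract_bow_contexts([t.form for t in sentence], c=2):
    print(f"  {pair.word:<12} -> {pair.context}")

# Note how "inhibited" keeps "thalidomide/SUB" and "formation/OBJ" as
# dependency contexts regardless of how many words sit between them,
# while the linear window would dilute them with "the", "of", ...
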