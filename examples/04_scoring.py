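"""How the evaluation works, on a hand-checkable toy prediction.

Token-level multi-class scoring with per-class P/R/F1 percentages, the
significance filter (classes with >= 10 gold instances), and the two
aggregates: macro-F1 (mean of per-class F1) and micro-F1 (summed F1
numerators over summed denominators, a per-class-average formula, distinct
from the conventional pooled-count micro-F1).  Run:

    python examples/04_scoring.py
"""

from deptrig.metrics import (
    count_matches,
    make_report,
    pooled_micro_f1,
    report_tsv,
    significant_classes,
)

# 30 tokens of gold vs predicted labels, NONE = not a trigger
gold = (
    ["Regulation"] * 10          # frequent class
    + ["Growth"] * 12            # frequent class
    + ["Synthesis"] * 2          # rare class: below the threshold of 10
    + ["NONE"] * 6
)
pred = (
    ["Regulation"] * 8 + ["NONE"] * 2        # misses 2 Regulation
    + ["Growth"] * 11 + ["Regulation"] * 1   # confuses 1 Growth
    + ["Synthesis"] * 2                      # rare class scored but filtered
    + ["NONE"] * 5 + ["Growth"] * 1          # one false alarm
)

counts = count_matches(gold, pred)
print("per-class (tp, fp, fn):")
for cls, c in sorted(counts.items()):
    print(f"  {cls:<12} {c}")

gold_counts = {c: gold.count(c) for c in ("Regulation", "Growth", "Synthesis")}
significant = significant_classes(gold_counts, threshold=10)
print(f"\nsignificant classes (>=10 gold): {significant}")

report = make_report(gold, pred, significant=significant)
print("\n" + report_tsv(report))

print(f"micro-F1 (summed-ratio form): {report.micro_f1:.2f}")
print(f"macro-F1 (mean of F1):        {report.macro_f1:.2f}")
print(f"pooled-count micro-F1:        {pooled_micro_f1(counts, significant):.2f}")
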