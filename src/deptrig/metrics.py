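"""Per-class and aggregate scoring of token-level trigger predictions.

Scoring is token-level multi-class: every token carries a gold and a
predicted class (``NONE`` for non-triggers, excluded from the class table).
Per class c:

    P = tp / (tp + fp),   R = tp / (tp + fn),   F1 = 2PR / (P + R)

all reported as percentages, with the convention that a zero denominator
yields 0.  Two aggregates over a chosen class set C are provided:

* ``macro_f1`` — the unweighted mean of per-class F1.
* ``micro_f1`` — the ratio of summed per-class F1 numerators to summed
  denominators, Σ(2·P·R)_i / Σ(P+R)_i.  Note this is a per-class-average
  formula, not the usual pooled-count micro-F1; the pooled variant is
  available separately as :func:`pooled_micro_f1`.

Aggregates are conventionally restricted to the "significant" classes —
those with at least 10 gold instances in the corpus — because rare classes
cannot be predicted reliably and would dominate the averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .standoff import NONE_LABEL

__all__ = [
    "ClassScores",
    "EvalReport",
    "count_matches",
    "prf",
    "significant_classes",
    "macro_f1",
    "micro_f1",
    "pooled_micro_f1",
    "make_report",
    "report_tsv",
]


@dataclass
class ClassScores:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


@dataclass
class EvalReport:
    """Per-class counts/scores plus aggregates over ``classes_evaluated``."""

    per_class: dict[str, ClassScores]
    classes_evaluated: list[str]
    micro_f1: float
    macro_f1: float
    dropped_gold: int = 0


def count_matches(
    gold: Sequence[str], predicted: Sequence[str], none_label: str = NONE_LABEL
) -> dict[str, tuple[int, int, int]]:
    """Token-level (tp, fp, fn) per class; ``none_label`` is not a class."""
    if len(gold) != len(predicted):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(predicted)} predicted")
    counts: dict[str, list[int]] = {}
    for g, p in zip(gold, predicted):
        if g == p:
            if g != none_label:
                counts.setdefault(g, [0, 0, 0])[0] += 1
            continue
        if p != none_label:
            counts.setdefault(p, [0, 0, 0])[1] += 1
        if g != none_label:
            counts.setdefault(g, [0, 0, 0])[2] += 1
    return {c: tuple(v) for c, v in counts.items()}  # type: ignore[misc]


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F1 as percentages; 0 on zero denominators."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2.0 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def significant_classes(
    class_counts: Mapping[str, int], threshold: int = 10
) -> list[str]:
    """Classes with at least ``threshold`` gold instances, in input order."""
    return [c for c, n in class_counts.items() if n >= threshold]


def _f1_table(report, classes: Iterable[str]) -> list[tuple[float, float, float]]:
    per_class = report.per_class if isinstance(report, EvalReport) else report
    rows = []
    for c in classes:
        sc = per_class.get(c)
        if sc is None:
            rows.append((0.0, 0.0, 0.0))
        elif isinstance(sc, ClassScores):
            rows.append((sc.precision, sc.recall, sc.f1))
        else:
            rows.append(tuple(sc))
    return rows


def macro_f1(report, classes: Sequence[str]) -> float:
    """Unweighted mean of per-class F1 over ``classes`` (percentage)."""
    if not classes:
        raise ValueError("macro average over an empty class set")
    rows = _f1_table(report, classes)
    return sum(f1 for _, _, f1 in rows) / len(rows)


def micro_f1(report, classes: Sequence[str]) -> float:
    """Σ(2PR)_i / Σ(P+R)_i over ``classes`` (percentage).

    This averages the per-class F1 fractions before dividing, the aggregate
    used for the headline scores; it is *not* the pooled-count micro-F1.
    """
    if not classes:
        raise ValueError("micro average over an empty class set")
    rows = _f1_table(report, classes)
    num = sum(2.0 * p * r for p, r, _ in rows)
    den = sum(p + r for p, r, _ in rows)
    return num / den if den else 0.0


def pooled_micro_f1(
    counts: Mapping[str, tuple[int, int, int]], classes: Sequence[str]
) -> float:
    """Conventional micro-F1 from pooled tp/fp/fn over ``classes``."""
    tp = sum(counts.get(c, (0, 0, 0))[0] for c in classes)
    fp = sum(counts.get(c, (0, 0, 0))[1] for c in classes)
    fn = sum(counts.get(c, (0, 0, 0))[2] for c in classes)
    return prf(tp, fp, fn)[2]


def make_report(
    gold: Sequence[str],
    predicted: Sequence[str],
    significant: Sequence[str] | None = None,
    class_counts: Mapping[str, int] | None = None,
    threshold: int = 10,
) -> EvalReport:
    """Score aligned gold/predicted token label sequences.

    ``significant`` fixes the aggregate class set C; otherwise it is derived
    from ``class_counts`` (or, failing that, gold counts in this very
    sequence) with the >= ``threshold`` rule.
    """
    counts = count_matches(gold, predicted)
    per_class = {
        c: ClassScores(tp, fp, fn, *prf(tp, fp, fn)) for c, (tp, fp, fn) in counts.items()
    }
    if significant is None:
        if class_counts is None:
            class_counts = {}
            for g in gold:
                if g != NONE_LABEL:
                    class_counts[g] = class_counts.get(g, 0) + 1
        significant = significant_classes(class_counts, threshold)
    sig = list(significant)
    if sig:
        micro = micro_f1(per_class, sig)
        macro = macro_f1(per_class, sig)
    else:
        micro = macro = 0.0
    return EvalReport(per_class=per_class, classes_evaluated=sig, micro_f1=micro, macro_f1=macro)


def report_tsv(report: EvalReport) -> str:
    """One row per class (class, tp, fp, fn, R%, P%, F1%) plus aggregate
    footer rows over the evaluated classes."""
    lines = ["class\ttp\tfp\tfn\tR(%)\tP(%)\tF1(%)"]
    for c in sorted(report.per_class):
        s = report.per_class[c]
        lines.append(
            f"{c}\t{s.tp}\t{s.fp}\t{s.fn}\t{s.recall:.2f}\t{s.precision:.2f}\t{s.f1:.2f}"
        )
    lines.append(f"micro_avg({len(report.classes_evaluated)} classes)\t\t\t\t\t\t{report.micro_f1:.2f}")
    lines.append(f"macro_avg({len(report.classes_evaluated)} classes)\t\t\t\t\t\t{report.macro_f1:.2f}")
    return "\n".join(lines) + "\n"
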