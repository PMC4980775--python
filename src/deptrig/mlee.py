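"""Reference figures for the MLEE (Multi-Level Event Extraction) corpus.

MLEE annotates biomedical events around angiogenesis across levels of
biological organisation, with 19 trigger classes grouped into anatomical,
molecular, general and planned categories.  The published per-class trigger
counts and the published aggregate scores of the main trigger-detection
systems on it are kept here so that the evaluation machinery can be
exercised against known numbers without downloading the corpus itself.
"""

from __future__ import annotations

__all__ = ["TRIGGER_CLASS_COUNTS", "CLASS_CATEGORIES", "REPORTED_MICRO", "REPORTED_MACRO"]

# trigger counts per class, in the corpus's published table order
TRIGGER_CLASS_COUNTS: dict[str, int] = {
    "Cell_proliferation": 43,
    "Development": 98,
    "Blood_vessel_development": 305,
    "Growth": 56,
    "Death": 36,
    "Breakdown": 23,
    "Remodeling": 10,
    "Synthesis": 4,
    "Gene_expression": 132,
    "Transcription": 7,
    "Catabolism": 4,
    "Phosphorylation": 3,
    "Dephosphorylation": 1,
    "Localization": 133,
    "Binding": 56,
    "Regulation": 178,
    "Positive_regulation": 312,
    "Negative_regulation": 223,
    "Planned_process": 175,
}

CLASS_CATEGORIES: dict[str, str] = {
    "Cell_proliferation": "Anatomical",
    "Development": "Anatomical",
    "Blood_vessel_development": "Anatomical",
    "Growth": "Anatomical",
    "Death": "Anatomical",
    "Breakdown": "Anatomical",
    "Remodeling": "Anatomical",
    "Synthesis": "Molecular",
    "Gene_expression": "Molecular",
    "Transcription": "Molecular",
    "Catabolism": "Molecular",
    "Phosphorylation": "Molecular",
    "Dephosphorylation": "Molecular",
    "Localization": "General",
    "Binding": "General",
    "Regulation": "General",
    "Positive_regulation": "General",
    "Negative_regulation": "General",
    "Planned_process": "Planned",
}

# published aggregate scores over significant classes: (recall %, precision %, F1 %)
REPORTED_MICRO: dict[str, tuple[float, float, float]] = {
    "pyysalo": (81.44, 69.48, 74.99),
    "zhou": (80.60, 74.23, 77.28),
    "dep_embedding": (83.62, 73.56, 78.27),
}

REPORTED_MACRO: dict[str, tuple[float, float, float]] = {
    "pyysalo": (78.04, 68.74, 73.09),
    "zhou": (79.18, 72.03, 75.43),
    "dep_embedding": (81.89, 72.56, 76.94),
}
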