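"""Canonical symptom vocabulary.

The Utrecht Symptom Diary (USD), a Dutch adaptation of the Edmonton Symptom
Assessment System, rates eleven symptoms on a 0--10 numeric rating scale.
Everything in this package that needs a tie-break or a reproducible ordering
refers to the listing order below, so the canonical order is defined once,
here.
"""

from __future__ import annotations

SYMPTOMS: tuple[str, ...] = (
    "pain",
    "sleeping problems",
    "dry mouth",
    "dysphagia",
    "lack of appetite",
    "constipation",
    "nausea",
    "shortness of breath",
    "fatigue",
    "anxiety",
    "depressed mood",
)

_CANON = {s.replace(" ", ""): s for s in SYMPTOMS}


def canonical(name: str) -> str:
    """Return the canonical form of a symptom label.

    Lookups are case-insensitive and ignore spaces, hyphens and underscores,
    so ``"Dry_Mouth"`` and ``"dry mouth"`` resolve to the same label.

    Raises
    ------
    KeyError
        If the name does not resolve to one of the eleven USD symptoms.
    """
    key = name.strip().lower().replace("_", "").replace("-", "").replace(" ", "")
    try:
        return _CANON[key]
    except KeyError:
        raise KeyError(f"unknown symptom label: {name!r}") from None


def canonical_index(name: str) -> int:
    """Position of a symptom in the canonical USD listing order."""
    return SYMPTOMS.index(canonical(name))
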