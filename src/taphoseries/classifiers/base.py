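"""Shared verdict type and deterministic tie handling."""

from __future__ import annotations

from dataclasses import dataclass

from ..series import CLASS_ORDER


@dataclass(frozen=True)
class ClassifierVerdict:
    """Outcome of classifying one query assemblage.

    ``probability`` is present only for the families that define one
    (KNN vote fraction, MTF backend class probability, ensemble scores).
    """

    algorithm: str
    predicted: str
    probability: float | None = None


def resolve_tie(candidates) -> str:
    """Break a label tie by the fixed class order (P before S).

    Determinism over hidden randomness: every tie in the package resolves the
    same way and is documented as doing so.
    """
    for label in CLASS_ORDER:
        if label in candidates:
            return label
    return sorted(candidates)[0]
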