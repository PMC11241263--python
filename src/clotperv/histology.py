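"""Clot composition validation and histologic type assignment.

Retrieved clots are quantified as relative area percentages of
fibrin/platelets, red blood cells (RBCs) and white blood cells (WBCs).
A clot is *RBC-rich* when its RBC percentage exceeds the fibrin/platelet
percentage by more than 15 percentage points, *fibrin/platelet-rich* in the
mirrored case, and *mixed* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CLOT_TYPES",
    "ClotComposition",
    "ClotType",
    "validate_composition",
    "classify_clot_type",
    "DEFAULT_MARGIN_PCT",
]

CLOT_TYPES = ("rbc_rich", "fibrin_platelet_rich", "mixed")

#: Dominance margin in percentage points for the rich/mixed rule.
DEFAULT_MARGIN_PCT = 15.0


@dataclass(frozen=True)
class ClotComposition:
    """Closed three-part composition in percent; components sum to 100."""

    fibrin_platelet_pct: float
    rbc_pct: float
    wbc_pct: float


@dataclass(frozen=True)
class ClotType:
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLOT_TYPES:
            raise ValueError(f"unknown clot type: {self.label!r}")


def validate_composition(
    fibrin: float, rbc: float, wbc: float, tolerance: float = 1.0
) -> ClotComposition:
    """Validate and close a (fibrin, RBC, WBC) percentage triple.

    Values must be non-negative and finite and their sum must lie within
    ``tolerance`` percentage points of 100; the triple is then rescaled to
    sum exactly 100.  A sum further from 100 indicates a data error and
    raises ``ValueError``.
    """
    values = np.array([fibrin, rbc, wbc], dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("composition percentages must be finite")
    if np.any(values < 0):
        raise ValueError("composition percentages must be non-negative")
    total = values.sum()
    if abs(total - 100.0) > tolerance:
        raise ValueError(
            f"composition sums to {total:g}, outside 100 ± {tolerance:g}"
        )
    values = values * (100.0 / total)
    return ClotComposition(
        fibrin_platelet_pct=float(values[0]),
        rbc_pct=float(values[1]),
        wbc_pct=float(values[2]),
    )


def classify_clot_type(
    composition: ClotComposition,
    margin: float = DEFAULT_MARGIN_PCT,
    relative: bool = False,
) -> ClotType:
    """Assign rbc_rich / fibrin_platelet_rich / mixed by component dominance.

    Default rule: a clot is RBC-rich iff ``rbc - fibrin > margin`` percentage
    points, fibrin/platelet-rich iff ``fibrin - rbc > margin``, else mixed.
    A difference of exactly ``margin`` is mixed (strict inequality).  The WBC
    fraction never influences the label.

    ``relative=True`` switches to a ratio reading for sensitivity analysis:
    dominance means exceeding the other component by a factor of
    ``1 + margin/100``.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    f, r = composition.fibrin_platelet_pct, composition.rbc_pct
    if relative:
        factor = 1.0 + margin / 100.0
        if r > factor * f:
            return ClotType("rbc_rich")
        if f > factor * r:
            return ClotType("fibrin_platelet_rich")
        return ClotType("mixed")
    if r - f > margin:
        return ClotType("rbc_rich")
    if f - r > margin:
        return ClotType("fibrin_platelet_rich")
    return ClotType("mixed")
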