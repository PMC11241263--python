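"""Thrombus attenuation increase (TAI) and dynamic perviousness classification.

Standard perviousness summarises contrast penetration into an occlusive clot as
the density increase from non-contrast CT to arterial-phase CTA,
``TAI = rho_CTA - rho_NCCT``.  With a third, late venous acquisition (CTV) the
trajectory of clot density across the three phases can be classified into four
contrast-uptake patterns:

``no_uptake``
    density change of 5 HU or less over all phases;
``late_uptake``
    change of 5 HU or less from unenhanced to arterial but more than 5 HU from
    unenhanced to the late phase;
``uptake_with_washout``
    more than 5 HU gain from unenhanced to arterial, followed by a drop of
    5 HU or more from arterial to late phase;
``uptake_without_washout``
    more than 5 HU gain from unenhanced to arterial with no such drop.

The first two patterns collapse to *non-pervious*, the last two to *pervious*
under the standard binary definition.

Conventions making the rule a total function over arbitrary triples (the
clinical wording leaves gaps) are documented in :func:`classify_dynamic`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import PhaseDensities

__all__ = [
    "CATEGORIES",
    "TAIResult",
    "PerviousnessCategory",
    "compute_tai",
    "classify_dynamic",
    "classify_dynamic_batch",
    "to_standard",
    "DEFAULT_THRESHOLD_HU",
]

#: Dynamic-perviousness labels in their conventional group order (1..4).
CATEGORIES = (
    "no_uptake",
    "late_uptake",
    "uptake_with_washout",
    "uptake_without_washout",
)

#: Density-change threshold in HU separating "no change" from uptake/washout.
DEFAULT_THRESHOLD_HU = 5.0

_NON_PERVIOUS = frozenset({"no_uptake", "late_uptake"})


@dataclass(frozen=True)
class TAIResult:
    """The three pairwise phase-density differences, in HU.

    ``tai_ctv_ncct == tai_cta_ncct + tai_ctv_cta`` holds exactly by
    construction.
    """

    tai_cta_ncct: float
    tai_ctv_cta: float
    tai_ctv_ncct: float


@dataclass(frozen=True)
class PerviousnessCategory:
    """A dynamic-perviousness label plus its binary standard collapse."""

    label: str
    standard: str

    def __post_init__(self) -> None:
        if self.label not in CATEGORIES:
            raise ValueError(f"unknown dynamic perviousness label: {self.label!r}")
        expected = to_standard(self.label)
        if self.standard != expected:
            raise ValueError(
                f"standard label {self.standard!r} inconsistent with {self.label!r}"
            )


def compute_tai(densities: PhaseDensities) -> TAIResult:
    """Compute the three phase-to-phase attenuation changes.

    Returns the unenhanced-to-arterial TAI (the standard perviousness
    measure), the arterial-to-venous change, and the unenhanced-to-venous
    change.  The third is computed as the sum of the first two so the
    additivity identity holds exactly in floating point.
    """
    d = densities
    for v in (d.rho_ncct, d.rho_cta, d.rho_ctv):
        if not np.isfinite(v):
            raise ValueError("phase densities must be finite")
    d_na = d.rho_cta - d.rho_ncct
    d_av = d.rho_ctv - d.rho_cta
    return TAIResult(tai_cta_ncct=d_na, tai_ctv_cta=d_av, tai_ctv_ncct=d_na + d_av)


def classify_dynamic(
    densities: PhaseDensities, threshold: float = DEFAULT_THRESHOLD_HU
) -> PerviousnessCategory:
    """Assign one of the four contrast-uptake patterns to a density triple.

    The decision tree (signed changes; ``t`` is the threshold, 5 HU by
    default):

    1. gain NCCT→CTA  > t: early uptake.  A drop CTA→CTV ≥ t yields
       ``uptake_with_washout``; any smaller drop — including a further rise —
       yields ``uptake_without_washout`` (categories 3 and 4 partition all
       early-uptake triples by the presence of a ≥ t washout drop).
    2. otherwise, gain NCCT→CTV > t yields ``late_uptake``.
    3. otherwise ``no_uptake``.

    Changes are signed increases: a density *decrease* of any size is never
    uptake, so strongly negative triples fall into ``no_uptake`` (or
    ``late_uptake`` if only the venous phase rose).  Boundaries are inclusive
    on the "or less" / "or more" sides: a change of exactly ``t`` is not
    uptake, a drop of exactly ``t`` is washout.

    Exactly one label is produced for every finite triple.
    """
    if threshold <= 0:
        # threshold = 0 degenerates gracefully: any positive change is uptake
        if threshold < 0:
            raise ValueError("threshold must be non-negative")
    tai = compute_tai(densities)
    label = _label_from_changes(tai.tai_cta_ncct, tai.tai_ctv_cta, threshold)
    return PerviousnessCategory(label=label, standard=to_standard(label))


def _label_from_changes(d_na: float, d_av: float, threshold: float) -> str:
    if d_na > threshold:
        drop = -d_av
        return "uptake_with_washout" if drop >= threshold else "uptake_without_washout"
    if d_na + d_av > threshold:  # unenhanced -> late venous
        return "late_uptake"
    return "no_uptake"


def classify_dynamic_batch(
    rho_ncct: np.ndarray,
    rho_cta: np.ndarray,
    rho_ctv: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD_HU,
) -> np.ndarray:
    """Vectorised :func:`classify_dynamic` over arrays of density triples.

    Returns an object array of labels; agrees elementwise with the scalar
    classifier.
    """
    n, a, v = (np.asarray(x, dtype=float) for x in (rho_ncct, rho_cta, rho_ctv))
    d_na = a - n
    d_nv = v - n
    drop = a - v
    early = d_na > threshold
    out = np.select(
        [
            early & (drop >= threshold),
            early,
            ~early & (d_nv > threshold),
        ],
        [
            "uptake_with_washout",
            "uptake_without_washout",
            "late_uptake",
        ],
        default="no_uptake",
    )
    return out


def to_standard(label: str) -> str:
    """Collapse a dynamic label to the binary standard-perviousness label."""
    if label not in CATEGORIES:
        raise ValueError(f"unknown dynamic perviousness label: {label!r}")
    return "non_pervious" if label in _NON_PERVIOUS else "pervious"
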