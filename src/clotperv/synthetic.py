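"""Synthetic stroke-clot cohorts and phantom three-phase CT volumes.

No public dataset pairs three-phase clot densities with clot histology, so
this module generates cohorts with the statistical structure the analysis
assumes: each patient gets a true contrast-uptake category, a phase-density
triple constructed to satisfy that category's defining inequalities with a
safety margin, a (fibrin, RBC, WBC) composition drawn from a Dirichlet whose
fibrin concentration can be coupled to the uptake category, and demographic /
outcome labels sampled from the empirical frequencies of a typical
large-vessel-occlusion thrombectomy cohort.

The phantom generator renders each patient's densities into simple
vessel-plus-clot NIfTI volumes so that the ROI-extraction stage can be
exercised end to end: ROI means measured on a zero-noise phantom reproduce
the generated densities exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .histology import ClotComposition, validate_composition
from .perviousness import CATEGORIES, DEFAULT_THRESHOLD_HU
from .roi import ClotROISet, PhaseVolume, PhaseDensities

__all__ = [
    "CohortConfig",
    "PatientRecord",
    "generate_cohort",
    "generate_phantom_volumes",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
    "SITE_FREQUENCIES",
    "ETIOLOGY_FREQUENCIES",
]

# Empirical level frequencies of a 39-patient thrombectomy cohort; used so
# that summary tables over synthetic cohorts look like real ones.
SITE_FREQUENCIES = {
    "MCA-M1": 23 / 39,
    "MCA-M2": 5 / 39,
    "ICA": 3 / 39,
    "ICA+MCA": 5 / 39,
    "MCA+ACA": 1 / 39,
    "basilar": 1 / 39,
    "PCA-P1": 1 / 39,
}
ETIOLOGY_FREQUENCIES = {
    "cardioembolic": 20 / 39,
    "unknown": 16 / 39,
    "large_artery_atherosclerosis": 2 / 39,
    "other_determined": 1 / 39,
}
MTICI_LEVELS = ("0", "2b", "2c", "3")

#: categories whose clots get the raised fibrin concentration
_FIBRIN_SHIFTED = ("no_uptake", "uptake_with_washout")


@dataclass
class CohortConfig:
    """Generator parameters; defaults emulate the study conditions.

    Units are HU for densities and percentage-scale fractions for
    compositions.  ``fibrin_effect`` is an additive shift to the Dirichlet
    fibrin concentration for the no-uptake and uptake-with-washout
    categories, encoding the direction that those clots are more often
    fibrin/platelet-rich than uptake-without-washout clots; 0 means
    composition is independent of category.
    """

    n_patients: int = 39
    category_probs: tuple = (0.20, 0.15, 0.35, 0.30)
    baseline_density_mean: float = 50.0
    baseline_density_sd: float = 8.0
    uptake_magnitude_mean: float = 20.0
    washout_drop_mean: float = 12.0
    density_noise_sd: float = 1.5
    fibrin_effect: float = 3.0
    composition_concentration: float = 12.0
    composition_base: tuple = (0.40, 0.50, 0.10)  # fibrin, rbc, wbc
    mtici_success_prob: float = 30 / 39
    mtici_category_coupling: float = 0.0  # success-prob shift for pervious clots
    female_prob: float = 19 / 39
    rtpa_prob: float = 29 / 39
    threshold_hu: float = DEFAULT_THRESHOLD_HU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        probs = np.asarray(self.category_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("category_probs must be 4 non-negative values summing to 1")
        for name in ("baseline_density_sd", "density_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fibrin_effect < 0:
            raise ValueError("fibrin_effect must be >= 0")
        if self.uptake_magnitude_mean <= self.threshold_hu:
            raise ValueError(
                "uptake_magnitude_mean must exceed the classification threshold "
                f"({self.threshold_hu} HU); generated categories would be ill-defined"
            )
        if self.margin >= self.threshold_hu:
            raise ValueError(
                "density_noise_sd too large: 2*sd margin must stay below the threshold"
            )
        if self.uptake_magnitude_mean <= self.threshold_hu + self.margin:
            raise ValueError(
                "uptake_magnitude_mean must exceed threshold plus the noise margin"
            )
        if not 0 <= self.mtici_success_prob <= 1:
            raise ValueError("mtici_success_prob must be in [0, 1]")

    @property
    def margin(self) -> float:
        """Safety margin (HU) between constructed triples and the thresholds."""
        return 2.0 * self.density_noise_sd


@dataclass
class PatientRecord:
    """One synthetic patient: imaging truth, composition and clinical labels."""

    patient_id: str
    true_category: str
    phase_densities: PhaseDensities
    composition: ClotComposition
    mtici: str
    site_of_occlusion: str
    etiology: str
    sex: str
    age: int
    nihss: int
    rtpa: bool


def _rng_for(config_seed: int, stream: int) -> np.random.Generator:
    # named substreams keyed off the root seed keep cohort draws stable when
    # other stages consume randomness
    return np.random.default_rng(np.random.SeedSequence(config_seed, spawn_key=(stream,)))


def _draw_densities(rng: np.random.Generator, cfg: CohortConfig, category: str) -> PhaseDensities:
    """Noiseless triple satisfying the category inequalities with margin ≥ 2·noise_sd."""
    t, m = cfg.threshold_hu, cfg.margin
    flat = t - m  # half-width of the "no change" band, strictly positive
    excess_up = max(cfg.uptake_magnitude_mean - t - m, 1e-6)
    excess_drop = max(cfg.washout_drop_mean - t - m, 1e-6)

    ncct = rng.normal(cfg.baseline_density_mean, cfg.baseline_density_sd)
    if category == "no_uptake":
        d_na = rng.uniform(-flat, flat)
        d_nv = rng.uniform(-flat, flat)
        cta, ctv = ncct + d_na, ncct + d_nv
    elif category == "late_uptake":
        d_na = rng.uniform(-flat, flat)
        d_nv = t + m + rng.exponential(excess_up)
        cta, ctv = ncct + d_na, ncct + d_nv
    elif category == "uptake_with_washout":
        d_na = t + m + rng.exponential(excess_up)
        drop = t + m + rng.exponential(excess_drop)
        cta = ncct + d_na
        ctv = cta - drop
    elif category == "uptake_without_washout":
        d_na = t + m + rng.exponential(excess_up)
        d_av = rng.uniform(-flat, flat)
        cta = ncct + d_na
        ctv = cta + d_av
    else:  # pragma: no cover
        raise ValueError(category)
    return PhaseDensities(rho_ncct=float(ncct), rho_cta=float(cta), rho_ctv=float(ctv))


def _draw_composition(rng: np.random.Generator, cfg: CohortConfig, category: str) -> ClotComposition:
    alpha = cfg.composition_concentration * np.asarray(cfg.composition_base, dtype=float)
    if category in _FIBRIN_SHIFTED:
        alpha = alpha.copy()
        alpha[0] += cfg.fibrin_effect
    pct = 100.0 * rng.dirichlet(alpha)
    return validate_composition(*pct)


def _draw_mtici(rng: np.random.Generator, cfg: CohortConfig, category: str) -> str:
    p = cfg.mtici_success_prob
    if category in ("uptake_with_washout", "uptake_without_washout"):
        p = min(1.0, max(0.0, p + cfg.mtici_category_coupling))
    if rng.random() < p:
        return "2c" if rng.random() < 0.5 else "3"
    return "2b" if rng.random() < 7 / 9 else "0"


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate ``config.n_patients`` synthetic patients.

    Deterministic: the same config (including seed) yields an identical
    cohort.  Phase-density triples are noiseless category exemplars; the
    configured measurement noise enters only when phantom volumes are
    rendered, so classifying a record's own densities always recovers its
    true category.
    """
    rng = _rng_for(config.seed, stream=0)
    site_levels = list(SITE_FREQUENCIES)
    site_p = np.array(list(SITE_FREQUENCIES.values()))
    etio_levels = list(ETIOLOGY_FREQUENCIES)
    etio_p = np.array(list(ETIOLOGY_FREQUENCIES.values()))

    records = []
    width = max(3, len(str(config.n_patients)))
    for i in range(config.n_patients):
        category = CATEGORIES[rng.choice(4, p=np.asarray(config.category_probs, float))]
        rec = PatientRecord(
            patient_id=f"P{i:0{width}d}",
            true_category=category,
            phase_densities=_draw_densities(rng, config, category),
            composition=_draw_composition(rng, config, category),
            mtici=_draw_mtici(rng, config, category),
            site_of_occlusion=site_levels[rng.choice(len(site_levels), p=site_p / site_p.sum())],
            etiology=etio_levels[rng.choice(len(etio_levels), p=etio_p / etio_p.sum())],
            sex="female" if rng.random() < config.female_prob else "male",
            age=int(np.clip(np.round(rng.normal(71, 17)), 18, 99)),
            nihss=int(np.clip(np.round(rng.normal(14, 4)), 0, 42)),
            rtpa=bool(rng.random() < config.rtpa_prob),
        )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Phantom rendering

_BACKGROUND_HU = 35.0
_VESSEL_RADIUS_MM = 1.5
_CLOT_LENGTH_MM = 8.0
_ROI_SPACING_MM = 2.0
_ROI_DIAMETER_MM = 1.0
_LUMEN_HU = {"NCCT": 45.0, "CTA": 240.0, "CTV": 120.0}


def generate_phantom_volumes(
    record: PatientRecord,
    shape: Sequence[int] = (48, 48, 48),
    voxel_size: float = 0.5,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, PhaseVolume], ClotROISet]:
    """Render one patient's three phase volumes plus the clot ROI set.

    Geometry: soft-tissue background, a straight vessel along the x axis
    through the volume center, and a clot segment occupying the central
    8 mm of the vessel.  Clot voxels take the record's per-phase density;
    i.i.d. Gaussian noise of ``noise_sd`` HU is added to every voxel.  Three
    1 mm spherical ROIs are placed 2 mm apart along the clot axis, fully
    inside the clot, so zero-noise extraction reproduces the record's
    densities exactly.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 2 for s in shape):
        raise ValueError("shape must be three positive voxel counts")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    extent = np.array(shape) * voxel_size
    needed = _CLOT_LENGTH_MM + 2 * _ROI_DIAMETER_MM
    if extent[0] < needed or extent[1] < 4 * _VESSEL_RADIUS_MM or extent[2] < 4 * _VESSEL_RADIUS_MM:
        raise ValueError(
            f"volume extent {extent} mm cannot fit an {_CLOT_LENGTH_MM} mm clot "
            "with its ROIs and vessel"
        )
    if rng is None:
        rng = np.random.default_rng(0)

    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    centers = [np.arange(s) * voxel_size for s in shape]
    X, Y, Z = np.meshgrid(*centers, indexing="ij")
    mid = (np.array(shape) - 1) * voxel_size / 2.0

    radial = np.sqrt((Y - mid[1]) ** 2 + (Z - mid[2]) ** 2)
    in_vessel = radial <= _VESSEL_RADIUS_MM
    in_clot = in_vessel & (np.abs(X - mid[0]) <= _CLOT_LENGTH_MM / 2.0)

    densities = {
        "NCCT": record.phase_densities.rho_ncct,
        "CTA": record.phase_densities.rho_cta,
        "CTV": record.phase_densities.rho_ctv,
    }
    volumes = {}
    for phase in ("NCCT", "CTA", "CTV"):
        vox = np.full(shape, _BACKGROUND_HU)
        vox[in_vessel] = _LUMEN_HU[phase]
        vox[in_clot] = densities[phase]
        if noise_sd > 0:
            vox = vox + rng.normal(0.0, noise_sd, size=shape)
        volumes[phase] = PhaseVolume(voxels=vox, affine=affine, phase_label=phase)

    rois = ClotROISet(
        rois=[
            (np.array([mid[0] + k * _ROI_SPACING_MM, mid[1], mid[2]]), _ROI_DIAMETER_MM)
            for k in (-1, 0, 1)
        ]
    )
    return volumes, rois


# ---------------------------------------------------------------------------
# Tabular I/O

def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten records to one row per patient."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "true_category": r.true_category,
                "rho_ncct": r.phase_densities.rho_ncct,
                "rho_cta": r.phase_densities.rho_cta,
                "rho_ctv": r.phase_densities.rho_ctv,
                "fibrin_platelet_pct": r.composition.fibrin_platelet_pct,
                "rbc_pct": r.composition.rbc_pct,
                "wbc_pct": r.composition.wbc_pct,
                "mtici": r.mtici,
                "site_of_occlusion": r.site_of_occlusion,
                "etiology": r.etiology,
                "sex": r.sex,
                "age": r.age,
                "nihss": r.nihss,
                "rtpa": r.rtpa,
            }
        )
    return pd.DataFrame(rows)


def write_cohort_csv(records: list[PatientRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"mtici": str})
    required = {"patient_id", "rho_ncct", "rho_cta", "rho_ctv"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
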