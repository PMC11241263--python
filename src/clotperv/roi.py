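"""Spherical-ROI density measurement on co-registered three-phase CT volumes.

Clot density is measured by placing three spherical regions of interest of
1 mm diameter along the visible clot on each phase (NCCT, CTA, CTV).  The
mean HU is computed per ROI first, then the three ROI means are averaged —
unweighted — into a single per-phase density.  Volumes are NIfTI-1 with a
world-coordinate affine in millimetres; co-registration is a precondition
checked here as grid identity, not performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.affines import apply_affine

__all__ = [
    "PHASES",
    "PhaseVolume",
    "ClotROISet",
    "PhaseDensities",
    "read_volume",
    "write_volume",
    "sample_sphere",
    "extract_phase_densities",
    "read_roi_csv",
    "write_roi_csv",
]

PHASES = ("NCCT", "CTA", "CTV")

# mm slack on sphere membership so exact-boundary voxels are included
# deterministically despite floating-point affine round trips.
_MEMBERSHIP_EPS = 1e-9


@dataclass
class PhaseVolume:
    """A single CT phase: HU voxel grid plus voxel-to-world affine (mm)."""

    voxels: np.ndarray
    affine: np.ndarray
    phase_label: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        if self.phase_label not in PHASES:
            raise ValueError(f"phase_label must be one of {PHASES}")


@dataclass
class ClotROISet:
    """Spherical ROIs along the clot: (center in world mm, diameter in mm)."""

    rois: list = field(default_factory=list)  # [(np.ndarray(3), float), ...]

    def __post_init__(self) -> None:
        cleaned = []
        for center, diameter in self.rois:
            center = np.asarray(center, dtype=float)
            if center.shape != (3,):
                raise ValueError("ROI center must be a 3-vector (world mm)")
            if not diameter > 0:
                raise ValueError("ROI diameter must be positive")
            cleaned.append((center, float(diameter)))
        self.rois = cleaned

    def __len__(self) -> int:
        return len(self.rois)


@dataclass(frozen=True)
class PhaseDensities:
    """Mean clot density per phase, each the mean of the three ROI means."""

    rho_ncct: float
    rho_cta: float
    rho_ctv: float


def read_volume(path: str | Path, phase_label: str) -> PhaseVolume:
    """Load a NIfTI-1 phase volume.

    Scale slope/intercept stored in the header are applied, so returned
    voxels are in HU regardless of the on-disk integer encoding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.ndim}D")
    data = np.asarray(img.get_fdata(), dtype=float)
    return PhaseVolume(voxels=data, affine=np.asarray(img.affine), phase_label=phase_label)


def write_volume(volume: PhaseVolume, path: str | Path) -> None:
    """Write a phase volume as NIfTI-1 (float32 voxels, mm affine)."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), volume.affine)
    nib.save(img, str(path))


def sample_sphere(
    volume: PhaseVolume, center: Sequence[float], diameter: float
) -> tuple[float, int]:
    """Mean HU over voxels whose centers fall within a world-space sphere.

    Membership rule: a voxel belongs to the ROI iff its center lies within
    ``diameter / 2`` (inclusive) of ``center`` in world coordinates.  Partial
    volumes are not weighted.  If the sphere is so small relative to the grid
    that it captures no voxel center, the nearest voxel is used instead and a
    warning is emitted — 1 mm ROIs on sub-millimetre CT necessarily operate
    near grid resolution.

    Returns ``(mean_hu, n_voxels)``.
    """
    center = np.asarray(center, dtype=float)
    if center.shape != (3,):
        raise ValueError("center must be a world-mm 3-vector")
    if not diameter > 0:
        raise ValueError("diameter must be positive")
    radius = diameter / 2.0

    inv = np.linalg.inv(volume.affine)
    c_vox = apply_affine(inv, center)
    shape = np.array(volume.voxels.shape)
    if np.any(c_vox < -0.5) or np.any(c_vox > shape - 0.5):
        raise ValueError("sphere center lies outside the volume")

    # Conservative bounding box in index space: the radius expressed in voxel
    # units along each axis, padded by one voxel.
    spacing = np.linalg.norm(volume.affine[:3, :3], axis=0)
    lo = np.maximum(np.floor(c_vox - radius / spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(c_vox + radius / spacing).astype(int) + 1, shape - 1)

    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = apply_affine(volume.affine, idx)
    dist = np.linalg.norm(world - center, axis=1)
    inside = dist <= radius + _MEMBERSHIP_EPS

    if not np.any(inside):
        warnings.warn(
            "sphere ROI captured no voxel centers; falling back to nearest voxel",
            stacklevel=2,
        )
        nearest = np.clip(np.round(c_vox).astype(int), 0, shape - 1)
        return float(volume.voxels[tuple(nearest)]), 1

    members = idx[inside]
    values = volume.voxels[members[:, 0], members[:, 1], members[:, 2]]
    return float(np.mean(values)), int(inside.sum())


def extract_phase_densities(
    ncct: PhaseVolume, cta: PhaseVolume, ctv: PhaseVolume, rois: ClotROISet
) -> PhaseDensities:
    """Per-phase clot density: mean of the per-ROI means.

    The three volumes must share grid shape and affine (co-registration is
    assumed done upstream).  Per phase, each ROI's mean HU is computed first
    and the unweighted mean of the ROI means is returned — ROIs with more
    voxels do not get more weight.
    """
    vols = {"NCCT": ncct, "CTA": cta, "CTV": ctv}
    shapes = {v.voxels.shape for v in vols.values()}
    if len(shapes) != 1:
        raise ValueError(f"phase volumes are on different grids: {shapes}")
    ref = ncct.affine
    for label, v in vols.items():
        if not np.allclose(v.affine, ref, atol=1e-6):
            raise ValueError(f"{label} affine differs from NCCT: volumes not co-registered")
    if len(rois) == 0:
        raise ValueError("ROI set is empty")

    means = {}
    for label, vol in vols.items():
        roi_means = [sample_sphere(vol, center, diameter)[0] for center, diameter in rois.rois]
        means[label] = float(np.mean(roi_means))
    return PhaseDensities(rho_ncct=means["NCCT"], rho_cta=means["CTA"], rho_ctv=means["CTV"])


def read_roi_csv(path: str | Path) -> ClotROISet:
    """Read an ROI set from CSV with columns x_mm, y_mm, z_mm, diameter_mm."""
    df = pd.read_csv(path)
    required = {"x_mm", "y_mm", "z_mm", "diameter_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI CSV missing columns: {sorted(missing)}")
    rois = [
        (np.array([row.x_mm, row.y_mm, row.z_mm]), float(row.diameter_mm))
        for row in df.itertuples()
    ]
    return ClotROISet(rois=rois)


def write_roi_csv(rois: ClotROISet, path: str | Path) -> None:
    rows = [
        {"x_mm": c[0], "y_mm": c[1], "z_mm": c[2], "diameter_mm": d}
        for c, d in rois.rois
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
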