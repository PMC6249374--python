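"""Probabilistic occurrence maps from cohorts of binary masks.

The atlas construction is: optionally smooth each subject's binary mask with
a Gaussian kernel (FWHM in mm; 3 mm is the convention for sulcal casts, none
for the larger cortical/hippocampal structures), average voxelwise across
subjects so each voxel holds the fraction of subjects whose structure covers
it, then threshold at a fraction (5% for display/blob definition, 25% for a
high-overlap sensitivity analysis) to obtain a *blob* — the voxel set the
group-level structure occupies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import LabeledVolume, SubjectMask

__all__ = [
    "ProbabilityMap",
    "Blob",
    "fwhm_to_sigma",
    "smooth_mask",
    "build_probability_map",
    "threshold_map",
]

#: FWHM = sigma * 2*sqrt(2*ln 2)
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

# Gaussian truncation radius in sigmas.  6 sigma keeps the discarded tail
# mass below ~2e-9 per axis so total mass is conserved to relative 1e-6.
_TRUNCATE = 6.0


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a kernel FWHM in mm."""
    return (fwhm_mm / _FWHM_FACTOR) / np.asarray(voxel_size_mm, dtype=float)


@dataclass
class ProbabilityMap:
    """Voxelwise occurrence fractions in [0, 1] over a cohort."""

    volume: LabeledVolume
    n_subjects: int
    smoothing_fwhm: float = 0.0
    structure: str | None = None
    hemisphere: str | None = None

    def __post_init__(self):
        data = self.volume.data
        if data.min() < -1e-9 or data.max() > 1 + 1e-9:
            raise ValueError("probability map values must lie in [0, 1]")


@dataclass
class Blob:
    """Voxels of a probability map surviving a fraction threshold."""

    voxel_indices: np.ndarray  # (n, 3) int
    affine: np.ndarray
    threshold: float
    shape: tuple = None

    def __post_init__(self):
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        if self.voxel_indices.size == 0:
            raise ValueError("blob is empty")
        if self.voxel_indices.ndim != 2 or self.voxel_indices.shape[1] != 3:
            raise ValueError("voxel_indices must be (n, 3)")
        if self.shape is not None and (
            np.any(self.voxel_indices < 0)
            or np.any(self.voxel_indices >= np.asarray(self.shape))
        ):
            raise ValueError("blob indices outside grid")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    def world_coordinates(self) -> np.ndarray:
        """(n, 3) world-mm coordinates of member voxel centers."""
        idx = self.voxel_indices.astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def to_volume(self) -> LabeledVolume:
        if self.shape is None:
            raise ValueError("blob carries no grid shape")
        data = np.zeros(self.shape, dtype=np.uint8)
        data[tuple(self.voxel_indices.T)] = 1
        return LabeledVolume(data, self.affine)


def _as_volume(mask) -> LabeledVolume:
    return mask.volume if isinstance(mask, SubjectMask) else mask


def smooth_mask(mask, fwhm: float) -> LabeledVolume:
    """Gaussian-smooth a binary mask; FWHM given in mm, converted per axis.

    Boundary handling is constant-zero padding, so the occurrence
    interpretation is conserved for structures lying well inside the grid
    (>= 2*FWHM from the edge); total mass is conserved to relative 1e-6.
    ``fwhm=0`` returns the input volume unchanged.
    """
    vol = _as_volume(mask)
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return vol
    sigma = fwhm_to_sigma(fwhm, vol.voxel_size)
    smoothed = ndimage.gaussian_filter(
        vol.data.astype(np.float64), sigma=sigma, mode="constant", cval=0.0,
        truncate=_TRUNCATE,
    )
    return LabeledVolume(smoothed, vol.affine)


def build_probability_map(
    masks,
    smoothing_fwhm: float = 0.0,
    structure: str | None = None,
    hemisphere: str | None = None,
) -> ProbabilityMap:
    """Average per-subject (optionally smoothed) masks into an occurrence map.

    Without smoothing every voxel value is exactly k/N, the fraction of the N
    subjects whose mask contains the voxel.
    """
    vols = [_as_volume(m) for m in masks]
    if not vols:
        raise ValueError("need at least one mask")
    ref = vols[0]
    bad = [i for i, v in enumerate(vols[1:], start=1) if not ref.same_grid(v)]
    if bad:
        raise ValueError(f"masks on mismatched grids at positions {bad}")
    acc = np.zeros(ref.shape, dtype=np.float64)
    for v in vols:
        acc += smooth_mask(v, smoothing_fwhm).data if smoothing_fwhm > 0 else v.data
    acc /= len(vols)
    np.clip(acc, 0.0, 1.0, out=acc)
    return ProbabilityMap(
        LabeledVolume(acc, ref.affine),
        n_subjects=len(vols),
        smoothing_fwhm=smoothing_fwhm,
        structure=structure,
        hemisphere=hemisphere,
    )


def threshold_map(pmap: ProbabilityMap, fraction: float) -> Blob:
    """Keep voxels present in at least ``fraction`` of subjects (inclusive >=)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    data = pmap.volume.data
    idx = np.argwhere(data >= fraction)
    if idx.size == 0:
        raise ValueError(f"blob empty at threshold {fraction}")
    return Blob(idx, pmap.volume.affine, threshold=fraction, shape=data.shape)
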