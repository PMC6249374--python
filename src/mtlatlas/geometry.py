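"""Geometric summaries of blobs and masks.

Bounding-box extrema (the per-axis min/max world coordinates of occupied
voxel centers: mediolateral x, rostrocaudal y, dorsoventral z), unweighted
centers of mass, and total-least-squares 3D line fits of centroid clouds
via SVD (the parametric line P = p0 + t*d minimizing summed squared
orthogonal distances).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .probmap import Blob
from .volume import LabeledVolume, SubjectMask

__all__ = ["BoundingBox", "LineFit", "bounding_box", "center_of_mass", "fit_odr_line"]

AXES = ("x", "y", "z")


@dataclass
class BoundingBox:
    """Per-axis world-mm extrema of occupied voxel centers."""

    min_mm: np.ndarray  # (3,)
    max_mm: np.ndarray  # (3,)

    def __post_init__(self):
        self.min_mm = np.asarray(self.min_mm, dtype=float)
        self.max_mm = np.asarray(self.max_mm, dtype=float)
        if np.any(self.min_mm > self.max_mm):
            raise ValueError("bounding box min exceeds max")

    def contains(self, point, atol: float = 1e-9) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(
            np.all(p >= self.min_mm - atol) and np.all(p <= self.max_mm + atol)
        )

    def as_dict(self) -> dict:
        return {
            ax: {"min": float(self.min_mm[i]), "max": float(self.max_mm[i])}
            for i, ax in enumerate(AXES)
        }


@dataclass
class LineFit:
    """3D line P = p0 + t*d fit to a point cloud.

    ``p0`` is the cloud mean, ``d`` a unit direction (sign-canonicalized so
    the largest-magnitude component is positive), ``t_values`` the signed
    projections of the centered points onto d (mean zero), and ``rss`` the
    summed squared orthogonal distances of the points to the line.
    ``degenerate_direction`` flags a (near-)tie in the two leading singular
    values, i.e. an ill-determined direction.
    """

    p0: np.ndarray
    d: np.ndarray
    t_values: np.ndarray
    rss: float
    degenerate_direction: bool = False

    def __post_init__(self):
        self.p0 = np.asarray(self.p0, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if abs(np.linalg.norm(self.d) - 1.0) > 1e-9:
            raise ValueError("direction d must be a unit vector")
        if self.rss < -1e-9:
            raise ValueError("rss must be >= 0")


def _coords(obj) -> np.ndarray:
    """World coordinates of an object's occupied voxel centers."""
    if isinstance(obj, Blob):
        return obj.world_coordinates()
    if isinstance(obj, SubjectMask):
        obj = obj.volume
    if isinstance(obj, LabeledVolume):
        pts = obj.world_coordinates()
        if len(pts) == 0:
            raise ValueError("empty volume: no occupied voxels")
        return pts
    pts = np.asarray(obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected a Blob, mask/volume, or (n, 3) coordinates")
    return pts


def bounding_box(blob) -> BoundingBox:
    """Extrema of a blob/mask along the x, y and z axes (voxel centers)."""
    pts = _coords(blob)
    return BoundingBox(pts.min(axis=0), pts.max(axis=0))


def center_of_mass(obj) -> np.ndarray:
    """Unweighted mean world coordinate of occupied voxels (binary weighting)."""
    return _coords(obj).mean(axis=0)


def canonical_sign(d: np.ndarray) -> np.ndarray:
    """Flip d so its largest-|.| component is positive (ties: x before y
    before z); makes the SVD direction a deterministic function of the cloud."""
    d = np.asarray(d, dtype=float)
    k = int(np.argmax(np.abs(d)))  # argmax takes the first of tied maxima
    return -d if d[k] < 0 else d.copy()


def fit_odr_line(points, tie_rtol: float = 1e-9) -> LineFit:
    """Orthogonal-distance-regression line through a 3D point cloud.

    The direction is the dominant right singular vector of the centered
    point matrix, which minimizes the total squared orthogonal distance
    among all lines through the centroid (and hence among all lines).

    Raises
    ------
    ValueError
        For fewer than 2 points or an all-identical cloud.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need >= 2 points of dimension 3")
    p0 = pts.mean(axis=0)
    centered = pts - p0
    if np.allclose(centered, 0.0):
        raise ValueError("degenerate cloud: all points identical")
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    d = canonical_sign(vt[0])
    t_values = centered @ d
    total = float(np.sum(centered**2))
    rss = max(total - float(svals[0] ** 2), 0.0)
    degenerate = len(svals) > 1 and svals[1] >= svals[0] * (1.0 - tie_rtol)
    return LineFit(p0, d, t_values, rss, degenerate_direction=bool(degenerate))
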