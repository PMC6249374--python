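"""Volumes, affines and voxel/world coordinate conversion.

A :class:`LabeledVolume` is the carrier for every gridded object in the
package: binary structure masks, smoothed per-subject volumes and
probabilistic occurrence maps.  It pairs a 3D scalar array with a NIfTI-style
4x4 affine that maps 0-based voxel indices to world coordinates in
millimetres at voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledVolume",
    "SubjectMask",
    "STRUCTURES",
    "SULCAL_STRUCTURES",
    "HEMISPHERES",
    "default_affine",
]

#: Structure label vocabulary: the three medial-temporal sulci (rhinal sulcus,
#: rostral and caudal collateral sulcus), four MTL cortices and the three
#: hippocampal subparts along the long axis.
SULCAL_STRUCTURES = ("RS", "CSproper", "CSpost")
STRUCTURES = SULCAL_STRUCTURES + ("ERC", "PRC", "PHC", "TPC", "HH", "HB", "HT")
HEMISPHERES = ("L", "R")


def default_affine(translation=(-36.0, -76.0, -50.0), voxel_size=(1.0, 1.0, 1.0)):
    """RAS+ affine with 1 mm isotropic voxels by default.

    The default translation places a 72x96x72 grid over the medial temporal
    region of MNI space.
    """
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size)
    aff[:3, 3] = translation
    return aff


@dataclass
class LabeledVolume:
    """A 3D scalar grid with a voxel-index -> world-mm affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values (binary occupancy, smoothed occupancy, or occurrence
        fractions).
    affine : ndarray, shape (4, 4)
        Invertible voxel-to-world transform; world coordinates are continuous
        millimetres at voxel centers (NIfTI convention, 0-based indices).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=default_affine)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be strictly positive on all axes")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """mm per axis, from the column norms of the linear part."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid(self, other: "LabeledVolume", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    # ------------------------------------------------------------------
    # coordinate conversion
    # ------------------------------------------------------------------
    def voxel_to_world(self, index) -> np.ndarray:
        """World-mm coordinates of the center of voxel ``index``.

        ``index`` may be a single integer triple or an (n, 3) array.
        Out-of-bounds single indices raise ``IndexError``.
        """
        idx = np.asarray(index, dtype=float)
        single = idx.ndim == 1
        idx2 = np.atleast_2d(idx)
        if single:
            i = np.asarray(index)
            if np.any(i < 0) or np.any(i >= np.asarray(self.shape)):
                raise IndexError(f"voxel index {tuple(i)} outside grid {self.shape}")
        world = idx2 @ self.affine[:3, :3].T + self.affine[:3, 3]
        return world[0] if single else world

    def world_to_voxel(self, world) -> np.ndarray:
        """Continuous voxel coordinates of world-mm points (inverse affine)."""
        w = np.asarray(world, dtype=float)
        single = w.ndim == 1
        w2 = np.atleast_2d(w)
        inv = np.linalg.inv(self.affine)
        vox = w2 @ inv[:3, :3].T + inv[:3, 3]
        return vox[0] if single else vox

    def world_coordinates(self, indices=None) -> np.ndarray:
        """World coordinates of given voxel indices (default: all nonzero)."""
        if indices is None:
            indices = np.argwhere(self.data != 0)
        return self.voxel_to_world(np.asarray(indices, dtype=float))


@dataclass
class SubjectMask:
    """One subject x hemisphere x structure binary mask.

    ``conformation_type`` is the sulcal morphotype of the hemisphere the mask
    belongs to: 1 when the rhinal sulcus and the collateral sulcus proper are
    connected into one continuous fold, 2 when they are separated, 0 when
    unknown (non-sulcal structures, or unclassified input).
    """

    subject_id: str
    hemisphere: str
    structure: str
    volume: LabeledVolume
    conformation_type: int = 0

    def __post_init__(self):
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.conformation_type not in (0, 1, 2):
            raise ValueError("conformation_type must be 1, 2 or 0 (unknown)")
        data = self.volume.data
        uniq = np.unique(data)
        if not np.all(np.isclose(uniq, np.round(uniq), atol=1e-6)) or np.any(
            (np.round(uniq) != 0) & (np.round(uniq) != 1)
        ):
            raise ValueError(
                "non-binary mask: values outside {0,1} in range "
                f"[{data.min()}, {data.max()}]"
            )
        if not np.any(data):
            raise ValueError("empty mask: no nonzero voxel")
        # normalize storage to uint8 0/1
        self.volume = LabeledVolume(
            np.round(data).astype(np.uint8), self.volume.affine
        )

    @property
    def n_voxels(self) -> int:
        return int(self.volume.data.sum())
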