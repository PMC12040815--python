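"""Regular 3D scalar fields (HU, Gy, or binary masks) on a shared voxel geometry.

The package uses a single grid convention throughout: node-centred samples in a
right-handed world frame measured in millimetres, with +z pointing cranially.
The world position of voxel index ``(i, j, k)`` is ``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class VoxelGrid:
    """A regular 3D scalar field with per-axis spacing and a world origin.

    Parameters
    ----------
    data:
        3D array indexed ``[i, j, k]`` mapping to world axes ``(x, y, z)``.
    spacing:
        Voxel spacing in mm per axis (scalar or length-3).
    origin:
        World coordinate (mm) of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of a world position."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def extent_mm(self) -> np.ndarray:
        """World-space size of the grid, last voxel centre to first, per axis."""
        return (np.asarray(self.shape) - 1) * self.spacing

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (n_voxels, 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.index_to_world(idx)

    def contains_point(self, world: np.ndarray) -> bool:
        f = self.world_to_index(world)
        return bool(np.all(f >= 0) and np.all(f <= np.asarray(self.shape) - 1))

    def sample_linear(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the field at world positions (n, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        coords = ((pts - self.origin) / self.spacing).T
        return ndimage.map_coordinates(
            self.data.astype(float), coords, order=1, mode="nearest"
        )

    def sample_nearest(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel lookup at world positions (n, 3); used for masks."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.rint((pts - self.origin) / self.spacing).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return self.data[idx[:, 0], idx[:, 1], idx[:, 2]]

    def like(self, data: np.ndarray) -> "VoxelGrid":
        """A new grid with the same geometry and different data."""
        return VoxelGrid(data, self.spacing.copy(), self.origin.copy())

    # --- NIfTI round trip -------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(np.append(self.spacing, 1.0))
        affine[:3, 3] = self.origin
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VoxelGrid":
        img = nib.load(str(path))
        affine = img.affine
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        return cls(np.asarray(img.dataobj, dtype=float), spacing, affine[:3, 3])


def mask_world_coordinates(mask: VoxelGrid) -> np.ndarray:
    """World coordinates (n, 3) of the voxel centres inside a binary mask."""
    idx = np.argwhere(mask.data > 0.5)
    if idx.size == 0:
        raise ValueError("mask is empty")
    return mask.index_to_world(idx)
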