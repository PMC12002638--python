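"""Anisotropic voxel geometry.

Index order is (z, y, x) everywhere; physical coordinates are in nm.
The physical coordinate of voxel ``(k, j, i)`` is the *center* of that
voxel: ``origin + (k*dz, j*dy, i*dx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "STED_GRID_SPACING", "CONFOCAL_GRID_SPACING"]

# Acquisition geometry: ~20 nm pixels at 150 nm z-steps for STED channels,
# 100 nm pixels at 300 nm z-steps for confocal channels.
STED_GRID_SPACING = (150.0, 20.0, 20.0)
CONFOCAL_GRID_SPACING = (300.0, 100.0, 100.0)


@dataclass(frozen=True)
class VoxelGrid:
    """Sampling geometry of one image stack.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts ``(nz, ny, nx)``.
    spacing : tuple of float
        Voxel pitch ``(dz, dy, dx)`` in nm; all strictly positive.
    origin : tuple of float
        Physical nm coordinate of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must be length-3 (z, y, x)")
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"all voxel counts must be positive, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # -- conversions ---------------------------------------------------

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Physical nm coordinates of voxel centers for (possibly fractional) indices."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Fractional (z, y, x) voxel indices for physical nm coordinates."""
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def physical_to_nearest(self, pos: np.ndarray) -> np.ndarray:
        """Nearest integer voxel indices for physical nm coordinates (not clipped)."""
        return np.rint(self.physical_to_index(pos)).astype(np.int64)

    def contains_index(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx))
        shp = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < shp), axis=-1)

    # -- derived quantities --------------------------------------------

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx * 1e-9  # nm^3 -> um^3

    @property
    def pixel_area_um2(self) -> float:
        _, dy, dx = self.spacing
        return dy * dx * 1e-6  # nm^2 -> um^2

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        """Physical size (z, y, x) spanned by the voxel centers, in nm."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Physical nm coordinates of voxel centers along one axis (0=z,1=y,2=x)."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]
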