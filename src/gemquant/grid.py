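"""Voxel-grid containers.

A :class:`VoxelGrid` is a 3D scalar field with an isotropic physical voxel
size in nanometres; a :class:`BinaryMask` is the boolean counterpart. Data
arrays are indexed ``[z, y, x]`` (MRC section/row/column order); physical
coordinates are ``(x, y, z)`` in nm with the origin at the centre of the
corner voxel, so voxel index ``i`` along an axis sits at ``i * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, GeometryError

__all__ = ["VoxelGrid", "BinaryMask", "require_same_geometry"]


@dataclass
class VoxelGrid:
    """3D scalar field (tomogram, probability map) on an isotropic grid.

    Parameters
    ----------
    data : ndarray, indexed [z, y, x]
    voxel_size : float
        Edge length of a voxel in nm; must be positive and isotropic.
    """

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConfigError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ConfigError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)

    @property
    def extent_xyz(self) -> tuple[float, float, float]:
        """Physical position of the last voxel centre along each axis (nm)."""
        nx, ny, nz = self.shape_xyz
        return ((nx - 1) * self.voxel_size, (ny - 1) * self.voxel_size, (nz - 1) * self.voxel_size)

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates (z, y, x) in nm, broadcastable to data.shape."""
        nz, ny, nx = self.data.shape
        z = np.arange(nz, dtype=float)[:, None, None] * self.voxel_size
        y = np.arange(ny, dtype=float)[None, :, None] * self.voxel_size
        x = np.arange(nx, dtype=float)[None, None, :] * self.voxel_size
        return z, y, x

    def nm_to_voxel(self, coords_xyz: np.ndarray) -> np.ndarray:
        """Convert (n, 3) physical xyz coordinates to fractional voxel indices (z, y, x)."""
        c = np.atleast_2d(np.asarray(coords_xyz, dtype=float))
        return c[:, ::-1] / self.voxel_size


@dataclass
class BinaryMask(VoxelGrid):
    """Boolean field on a VoxelGrid geometry (structures, lamellae, labels)."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        super().__post_init__()

    @property
    def n_true(self) -> int:
        return int(self.data.sum())

    @property
    def volume_nm3(self) -> float:
        return self.n_true * self.voxel_size**3


def require_same_geometry(a: VoxelGrid, b: VoxelGrid, what: str = "grids") -> None:
    if a.data.shape != b.data.shape or not np.isclose(a.voxel_size, b.voxel_size):
        raise GeometryError(
            f"{what} have mismatched geometry: "
            f"{a.data.shape}@{a.voxel_size} vs {b.data.shape}@{b.voxel_size}"
        )
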