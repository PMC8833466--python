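"""Field-of-view geometries and world/voxel coordinate handling.

A geometry describes a regular axis-aligned acquisition grid: an in-plane
field of view, a voxel size, and a slice count. World coordinates are in
millimetres; the grid is centred on the world origin so that the same
anatomy can be imaged by different geometries (full vs reduced FOV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """A point or region falls outside a geometry, or a geometry is invalid."""


@dataclass(frozen=True)
class FOVGeometry:
    """An acquisition grid: in-plane FOV (mm), voxel size (mm), slice count.

    The implied matrix ``FOV / voxel`` must be a positive integer grid.
    The affine maps 0-based voxel indices (i, j, k) to world mm, with the
    grid centred on the origin and slices along the third axis.
    """

    name: str
    field_of_view_mm: tuple[float, float]
    voxel_size_mm: tuple[float, float, float]
    n_slices: int

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise GeometryError(f"n_slices must be >= 1, got {self.n_slices}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise GeometryError(f"voxel sizes must be > 0, got {self.voxel_size_mm}")
        for fov, vox in zip(self.field_of_view_mm, self.voxel_size_mm[:2]):
            n = fov / vox
            if fov <= 0 or abs(n - round(n)) > 1e-6:
                raise GeometryError(
                    f"FOV {fov} mm is not an integer multiple of voxel size {vox} mm"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return (
            round(self.field_of_view_mm[0] / self.voxel_size_mm[0]),
            round(self.field_of_view_mm[1] / self.voxel_size_mm[1]),
            self.n_slices,
        )

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm transform (invertible by construction)."""
        aff = np.eye(4)
        shape = self.shape
        for ax in range(3):
            aff[ax, ax] = self.voxel_size_mm[ax]
            aff[ax, 3] = -(shape[ax] - 1) / 2.0 * self.voxel_size_mm[ax]
        return aff

    def axis_coords(self, axis: int) -> np.ndarray:
        """World-mm coordinates of voxel centres along one axis."""
        n = self.shape[axis]
        v = self.voxel_size_mm[axis]
        return (np.arange(n) - (n - 1) / 2.0) * v

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk).astype(float)
        return ijk * np.asarray(self.voxel_size_mm) + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points (not rounded)."""
        xyz = np.atleast_2d(xyz).astype(float)
        return (xyz - self.affine[:3, 3]) / np.asarray(self.voxel_size_mm)

    def contains(self, xyz) -> bool:
        """Whether a world point lies inside the FOV box."""
        xyz = np.asarray(xyz, dtype=float)
        half = np.array(
            [
                self.field_of_view_mm[0] / 2.0,
                self.field_of_view_mm[1] / 2.0,
                self.n_slices * self.voxel_size_mm[2] / 2.0,
            ]
        )
        return bool(np.all(np.abs(xyz) <= half))

    def scaled(self, shape: tuple[int, int, int], name: str | None = None) -> "FOVGeometry":
        """Same voxel size on a smaller/larger grid (FOV = shape * voxel)."""
        return FOVGeometry(
            name=name or self.name,
            field_of_view_mm=(
                shape[0] * self.voxel_size_mm[0],
                shape[1] * self.voxel_size_mm[1],
            ),
            voxel_size_mm=self.voxel_size_mm,
            n_slices=shape[2],
        )


# The two acquisition geometries of the study protocol.  The full-FOV in-plane
# extent is taken as 420 x 363 mm so that the 3 mm voxels tile it exactly into
# the reconstructed 140 x 121 matrix.
FFOV = FOVGeometry("fFOV", field_of_view_mm=(420.0, 363.0), voxel_size_mm=(3.0, 3.0, 4.0), n_slices=43)
RFOV = FOVGeometry("rFOV", field_of_view_mm=(300.0, 300.0), voxel_size_mm=(2.5, 2.5, 3.0), n_slices=20)
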