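"""Regular 3-D sampling grids with RAS+ world affines.

A :class:`Grid` couples an array shape with a 4x4 voxel-to-world affine
(millimetres, RAS+ convention). All geometric reasoning in the acquisition
simulator and the super-resolution solver goes through these helpers so that
voxel indexing and world coordinates never get mixed up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "centered_grid"]


@dataclass(frozen=True)
class Grid:
    """A regular 3-D grid: array ``shape`` plus voxel-to-world ``affine``."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (norms of the affine's direction columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def axes(self) -> np.ndarray:
        """Unit direction vectors of the three grid axes, as columns."""
        return self.affine[:3, :3] / self.spacing[None, :]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel coordinates to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm coordinates to (fractional) voxel coordinates."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine[:3, :3])
        return (xyz - self.affine[:3, 3]) @ inv.T

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (n_voxels, 3), C order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(idx)

    def corners_world(self) -> np.ndarray:
        """World coordinates of the 8 outer corners of the field of view."""
        lo = -0.5
        his = np.asarray(self.shape, dtype=float) - 0.5
        pts = np.array(
            [[x, y, z] for x in (lo, his[0]) for y in (lo, his[1]) for z in (lo, his[2])]
        )
        return self.voxel_to_world(pts)

    def same_geometry(self, other: "Grid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


def centered_grid(shape, spacing) -> Grid:
    """Axis-aligned RAS+ grid of given shape/spacing centered on world origin."""
    shape = tuple(int(s) for s in np.atleast_1d(shape) * np.ones(3, dtype=int))
    spacing = np.asarray(spacing, dtype=float) * np.ones(3)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * spacing
    return Grid(shape, affine)
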