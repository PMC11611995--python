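"""Reference voxel grids and world/voxel coordinate transforms.

All user-facing coordinates are world millimetres; voxel indices are
0-based and internal.  The affine is the single source of spatial truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PhantomSpace:
    """An isotropic voxel grid standing in for a 2 mm template space.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis; each entry must be >= 8.
    voxel_size : float
        Isotropic voxel edge in mm.
    origin : tuple of float
        World coordinate of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 2.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    affine: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError(f"shape must be 3 entries >= 8, got {self.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = self.origin
        object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (N, 3) to continuous voxel coordinates."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (continuous or integer) voxel coordinates (N, 3) to world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World-mm bounding box covered by the voxel cells (lo, hi)."""
        lo = self.voxel_to_world(np.array([[-0.5, -0.5, -0.5]]))[0]
        hi = self.voxel_to_world(np.array(self.shape, dtype=float)[None] - 0.5)[0]
        return lo, hi

    def contains_world(self, points: np.ndarray) -> np.ndarray:
        """Boolean per point: does the point fall inside a grid cell."""
        vox = self.world_to_voxel(points)
        shape = np.array(self.shape)
        return np.all((vox >= -0.5) & (vox < shape - 0.5), axis=1)


def grids_match(affine_a: np.ndarray, affine_b: np.ndarray,
                shape_a: tuple, shape_b: tuple, atol: float = 1e-6) -> bool:
    """True when two volumes live on the same grid."""
    return tuple(shape_a) == tuple(shape_b) and np.allclose(
        affine_a, affine_b, atol=atol
    )
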