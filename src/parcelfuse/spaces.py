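"""Voxel spaces: coordinates, hemisphere labels and left/right mirror pairing.

A :class:`VoxelSpace` is the spatial substrate every other component indexes
into — synthetic worlds use small 2-D grids standing in for the template's
gray-matter voxels. The left/right mirror pairing is what the symmetric
arrangement model ties parcels across.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

LEFT, RIGHT, MIDLINE = "left", "right", "midline"


@dataclass
class VoxelSpace:
    """Voxel coordinates plus hemisphere labels and a mirror pairing.

    Parameters
    ----------
    coords : (P, d) float array
        Voxel coordinates in template units (Euclidean). Axis 0 is the
        left/right axis: negative = left, positive = right.
    hemisphere : (P,) array of {"left", "right", "midline"}
    mirror : (P,) int array
        ``mirror[i]`` is the index of the anatomically mirrored voxel;
        midline voxels may map to themselves.
    """

    coords: np.ndarray
    hemisphere: np.ndarray
    mirror: np.ndarray
    _dist: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        self.mirror = np.asarray(self.mirror, dtype=int)
        if self.coords.ndim != 2:
            raise ValueError("coords must be a P x d matrix")
        P = self.coords.shape[0]
        if self.hemisphere.shape != (P,) or self.mirror.shape != (P,):
            raise ValueError("hemisphere and mirror must have length P")
        if not np.array_equal(self.mirror[self.mirror], np.arange(P)):
            raise ValueError("mirror must be an involution")
        reflected = self.coords.copy()
        reflected[:, 0] *= -1
        if not np.allclose(self.coords[self.mirror], reflected, atol=1e-9):
            raise ValueError("mirrored voxels must have reflected coordinates")
        n_left = int(np.sum(self.hemisphere == LEFT))
        n_right = int(np.sum(self.hemisphere == RIGHT))
        if n_left != n_right:
            raise ValueError("left and right voxel counts must be equal")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def left(self) -> np.ndarray:
        """Indices of left-hemisphere voxels."""
        return np.flatnonzero(self.hemisphere == LEFT)

    @property
    def right(self) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == RIGHT)

    @property
    def midline(self) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == MIDLINE)

    def pairwise_distances(self) -> np.ndarray:
        """P x P Euclidean distance matrix (cached)."""
        if self._dist is None:
            self._dist = cdist(self.coords, self.coords)
        return self._dist


def make_symmetric_grid(width: int, height: int, spacing: float = 1.0) -> VoxelSpace:
    """Build a mirror-symmetric 2-D grid of ``width * height`` voxels.

    Columns left of the midline are labeled left, those right of it right;
    the mirror maps (x, y) to (-x, y). ``width`` must be even so the two
    halves are equal (no midline voxels by default — the synthetic worlds
    avoid the ambiguity of self-paired voxels).
    """
    if width % 2 != 0:
        raise ValueError("no symmetric split: width must be even")
    xs = (np.arange(width) - (width - 1) / 2.0) * spacing
    ys = (np.arange(height) - (height - 1) / 2.0) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    coords = np.column_stack([gx.ravel(), gy.ravel()])
    hemisphere = np.where(coords[:, 0] < 0, LEFT, RIGHT).astype(object)

    # mirror partner: same y-row, column reflected about the midline
    cols = np.tile(np.arange(width), height)
    rows = np.repeat(np.arange(height), width)
    mirror = rows * width + (width - 1 - cols)
    return VoxelSpace(coords=coords, hemisphere=hemisphere, mirror=mirror)
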