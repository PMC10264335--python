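"""Voxel grids, image volumes and attenuation maps.

World coordinates address voxel centres: voxel ``(i, j, k)`` of a grid with
corner ``origin`` and per-axis ``voxel_size`` is centred at
``origin + (index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    origin: Tuple[float, float, float]  # corner, mm
    voxel_size: Tuple[float, float, float]  # mm
    shape: Tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")

    @classmethod
    def centred(cls, center, voxel_size, shape) -> "VoxelGrid":
        center = np.asarray(center, dtype=np.float64)
        voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=np.float64), (3,))
        shape = np.asarray(shape, dtype=np.int64)
        origin = center - voxel_size * shape / 2.0
        return cls(tuple(origin), tuple(voxel_size), tuple(int(s) for s in shape))

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.voxel_size) * np.asarray(self.shape)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin)
        v = np.asarray(self.voxel_size)
        return tuple(
            o[ax] + (np.arange(self.shape[ax]) + 0.5) * v[ax] for ax in range(3)
        )

    def center_grid(self) -> np.ndarray:
        """(nx*ny*nz, 3) array of voxel-centre coordinates (C order)."""
        cx, cy, cz = self.voxel_centers()
        X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        o = np.asarray(self.origin)
        v = np.asarray(self.voxel_size)
        return np.floor((pts - o) / v).astype(np.int64)


@dataclass
class ImageVolume:
    grid: VoxelGrid
    values: np.ndarray  # (nx, ny, nz), non-negative
    units: str = "counts"

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError("values shape does not match grid")

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class MuMap:
    """Linear-attenuation map (1/mm) on a voxel grid."""

    grid: VoxelGrid
    mu: np.ndarray

    def __post_init__(self) -> None:
        if tuple(self.mu.shape) != tuple(self.grid.shape):
            raise ValueError("mu shape does not match grid")
        if (self.mu < 0).any():
            raise ValueError("mu must be non-negative")


def voxelise_mu_map(phantom, grid: VoxelGrid) -> MuMap:
    """511 keV attenuation of the highest-priority primitive at each voxel
    centre; zero outside the phantom."""
    pts = grid.center_grid()
    mu = phantom.mu_at(pts).reshape(grid.shape)
    return MuMap(grid, mu)
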