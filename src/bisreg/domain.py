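"""Spatial domains: masked voxel grids or vertex clouds with coordinates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpatialDomain:
    """A set of V spatial locations in d dimensions.

    Coordinates are kept in normalized units: the masked point cloud is
    affinely mapped into the unit box [0, 1]^d by shifting the minimum to the
    origin and dividing every axis by the *largest* axis extent, preserving
    the aspect ratio.  Kernel length scales are therefore unit-free fractions
    of the largest domain extent.

    Parameters
    ----------
    coords : (V, d) float array
        Normalized coordinates.
    voxel_ids : (V,) int array
        Labels linking each location back to the source image grid (flat
        voxel indices) or surface vertex indices.  Must be unique.
    grid_shape : tuple of int, optional
        Shape of the source image grid, when the domain came from a mask;
        used when writing maps back to volumes.
    """

    coords: np.ndarray
    voxel_ids: np.ndarray
    grid_shape: tuple | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be a V×d matrix")
        if self.coords.shape[0] < 2:
            raise ValueError("a spatial domain needs at least 2 locations")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=np.int64)
        if self.voxel_ids.shape != (self.coords.shape[0],):
            raise ValueError("voxel_ids must have length V")
        if np.unique(self.voxel_ids).size != self.voxel_ids.size:
            raise ValueError("voxel_ids must be unique")

    @property
    def n_locations(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_coords(
        cls,
        raw_coords: np.ndarray,
        voxel_ids: np.ndarray | None = None,
        normalize: bool = True,
        grid_shape: tuple | None = None,
    ) -> "SpatialDomain":
        """Build a domain from raw coordinates (e.g. voxel indices or mm)."""
        raw = np.asarray(raw_coords, dtype=float)
        if voxel_ids is None:
            voxel_ids = np.arange(raw.shape[0])
        coords = normalize_coords(raw) if normalize else raw
        return cls(coords=coords, voxel_ids=np.asarray(voxel_ids), grid_shape=grid_shape)

    @classmethod
    def from_mask(cls, mask: np.ndarray, normalize: bool = True) -> "SpatialDomain":
        """Build a domain from a binary mask array (any dimensionality).

        Locations are the voxel centers of nonzero mask entries, in index
        units before normalization; ``voxel_ids`` are flat indices into the
        mask grid (C order).
        """
        mask = np.asarray(mask).astype(bool)
        idx = np.argwhere(mask)
        if idx.shape[0] == 0:
            raise ValueError("mask is empty")
        flat = np.ravel_multi_index(tuple(idx.T), mask.shape)
        return cls.from_coords(
            idx.astype(float), voxel_ids=flat, normalize=normalize, grid_shape=mask.shape
        )

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-location values back onto the source grid."""
        if self.grid_shape is None:
            raise ValueError("domain has no source grid")
        out = np.full(int(np.prod(self.grid_shape)), fill, dtype=float)
        out[self.voxel_ids] = values
        return out.reshape(self.grid_shape)


def normalize_coords(raw: np.ndarray) -> np.ndarray:
    """Affinely map coordinates into [0,1]^d preserving aspect ratio."""
    raw = np.asarray(raw, dtype=float)
    lo = raw.min(axis=0)
    extent = raw.max(axis=0) - lo
    scale = extent.max()
    if scale <= 0:
        raise ValueError("degenerate coordinates: zero extent on every axis")
    return (raw - lo) / scale
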