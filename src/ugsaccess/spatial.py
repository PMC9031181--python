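"""Pairwise distances and catchment membership.

Distances are straight-line: great-circle (haversine) on a sphere of
radius 6,371,000 m for lon/lat input, or planar Euclidean when
coordinates are already projected meters. Catchment membership is
boundary-inclusive: a point at exactly d0 belongs to the catchment
(though the Gaussian kernel assigns it weight zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def haversine_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle distances in meters between two (n,2)/(m,2) lon-lat sets."""
    a = np.radians(np.atleast_2d(a))
    b = np.radians(np.atleast_2d(b))
    dlon = a[:, None, 0] - b[None, :, 0]
    dlat = a[:, None, 1] - b[None, :, 1]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(a[:, None, 1]) * np.cos(b[None, :, 1]) * np.sin(dlon / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def euclidean_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    d = a[:, None, :] - b[None, :, :]
    return np.sqrt((d * d).sum(axis=2))


@dataclass(frozen=True)
class DistanceMatrix:
    """Dense demand x supply distance matrix (meters) with its metric tag."""

    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("distances must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def pairwise_distances(
    demand_xy: np.ndarray, supply_xy: np.ndarray, metric: str = "haversine"
) -> DistanceMatrix:
    """Distances between every demand point (row) and supply point (column).

    Parameters
    ----------
    demand_xy, supply_xy
        (n, 2) arrays; (lon, lat) degrees for ``haversine``, planar
        meters for ``euclidean``.
    """
    demand_xy = np.asarray(demand_xy, dtype=float)
    supply_xy = np.asarray(supply_xy, dtype=float)
    if metric == "haversine":
        vals = haversine_matrix(demand_xy, supply_xy)
    elif metric == "euclidean":
        vals = euclidean_matrix(demand_xy, supply_xy)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(values=vals, metric=metric)


def catchment(dmatrix: DistanceMatrix, center_index: int, d0: float, axis: int = 0) -> np.ndarray:
    """Indices within the boundary-inclusive catchment (d <= d0) of one point.

    ``axis=0``: ``center_index`` is a demand row; returns supply indices.
    ``axis=1``: ``center_index`` is a supply column; returns demand indices.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if axis == 0:
        row = dmatrix.values[center_index, :]
    elif axis == 1:
        row = dmatrix.values[:, center_index]
    else:
        raise ValueError("axis must be 0 or 1")
    return np.nonzero(row <= d0)[0]


class GridIndex:
    """Uniform grid bucket index over planar points for radius queries.

    Returns exactly the same point sets as a dense scan (candidate cells
    are over-inclusive and then filtered by true distance); it only
    saves work when n is large and the radius is small relative to the
    extent.
    """

    def __init__(self, xy: np.ndarray, cell_size: float):
        if cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.xy = np.asarray(xy, dtype=float)
        self.cell = float(cell_size)
        self._buckets: dict[tuple[int, int], list[int]] = {}
        keys = np.floor(self.xy / self.cell).astype(int)
        for i, (kx, ky) in enumerate(keys):
            self._buckets.setdefault((int(kx), int(ky)), []).append(i)

    def query_radius(self, point: np.ndarray, radius: float) -> np.ndarray:
        """Indices of stored points with Euclidean distance <= radius."""
        point = np.asarray(point, dtype=float)
        lo = np.floor((point - radius) / self.cell).astype(int)
        hi = np.floor((point + radius) / self.cell).astype(int)
        cand: list[int] = []
        for kx in range(lo[0], hi[0] + 1):
            for ky in range(lo[1], hi[1] + 1):
                cand.extend(self._buckets.get((kx, ky), ()))
        if not cand:
            return np.array([], dtype=int)
        cand_arr = np.array(sorted(cand), dtype=int)
        d = np.sqrt(((self.xy[cand_arr] - point) ** 2).sum(axis=1))
        return cand_arr[d <= radius]
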