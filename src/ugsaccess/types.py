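"""Core domain records and run configuration.

Coordinates are WGS84 longitude/latitude degrees by default; a
``planar`` flag on :class:`RunConfig` declares that coordinates are
already projected planar meters, in which case Euclidean distance is
the natural metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Search radii tested in the analysis, meters (walking/cycling: 1 km,
#: 2.5 km; driving: 5 km, 10 km).
DEFAULT_RADII_M = (1_000.0, 2_500.0, 5_000.0, 10_000.0)

#: House-price band edges (yuan/m²) bounding five contiguous tiers:
#: 500–5500, 5501–7640, 7641–11038, 11039–23902, 23903–194667.
DEFAULT_PRICE_BREAKPOINTS = (5_500.0, 7_640.0, 11_038.0, 23_902.0)


@dataclass(frozen=True)
class Community:
    """A residential demand point: households H_i living at one location."""

    id: str
    lon: float
    lat: float
    households: int
    price: float  # yuan per m² floor area
    city_id: str = "city"

    def __post_init__(self) -> None:
        if self.households < 1:
            raise ValueError(f"community {self.id}: households must be >= 1")
        if not self.price > 0:
            raise ValueError(f"community {self.id}: price must be positive")
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise ValueError(f"community {self.id}: non-finite coordinates")


@dataclass(frozen=True)
class GreenSpace:
    """A green-space supply point with service capacity S_j = area in m²."""

    id: str
    lon: float
    lat: float
    area_m2: float
    city_id: str = "city"

    def __post_init__(self) -> None:
        if not self.area_m2 > 0:
            raise ValueError(f"green space {self.id}: area must be positive")
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise ValueError(f"green space {self.id}: non-finite coordinates")

    @property
    def area_ha(self) -> float:
        return self.area_m2 / 10_000.0


@dataclass
class RunConfig:
    """Parameters of one analysis run.

    Attributes
    ----------
    radii_m
        Catchment radii d0, meters, strictly ascending.
    distance_metric
        ``"haversine"`` (lon/lat on a 6,371,000 m sphere) or
        ``"euclidean"`` (planar meters).
    planar
        Coordinates are already projected planar meters.
    traditional_variant
        ``"per_household"`` (reachable supply per own household, i.e.
        2SFCA without cross-community competition; same units as
        2SFCA), ``"decayed_per_household"`` (kernel-weighted reachable
        supply per own household) or ``"decayed_supply"`` (no
        household normalization).
    price_breakpoints
        Ascending interior edges of the house-price tiers.
    min_nonzero_share
        Reserved threshold on the share of communities with nonzero
        accessibility below which a city may be flagged; the standard
        exclusion (total accessibility zero) applies regardless.
    min_communities
        Minimum community count for a city to enter Gini reporting.
    seed
        Seed for any stochastic step (synthetic generation).
    """

    radii_m: Sequence[float] = DEFAULT_RADII_M
    distance_metric: str = "haversine"
    planar: bool = False
    traditional_variant: str = "per_household"
    price_breakpoints: Sequence[float] = DEFAULT_PRICE_BREAKPOINTS
    min_nonzero_share: float = 0.0
    min_communities: int = 2
    seed: int = 0
    column_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        radii = [float(r) for r in self.radii_m]
        if not radii or any(r <= 0 for r in radii):
            raise ValueError("radii must be strictly positive")
        if any(b >= a for a, b in zip(radii[1:], radii[:-1])):
            raise ValueError("radii must be strictly ascending")
        bp = [float(b) for b in self.price_breakpoints]
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("price breakpoints must be strictly ascending")
        if self.distance_metric not in ("haversine", "euclidean"):
            raise ValueError(f"unknown metric {self.distance_metric!r}")
        if self.traditional_variant not in (
            "per_household", "decayed_per_household", "decayed_supply"
        ):
            raise ValueError(
                f"unknown traditional variant {self.traditional_variant!r}"
            )
        self.radii_m = tuple(radii)
        self.price_breakpoints = tuple(bp)

    @property
    def effective_metric(self) -> str:
        return "euclidean" if self.planar else self.distance_metric


def coords(items: Sequence[Community] | Sequence[GreenSpace]) -> np.ndarray:
    """(n, 2) array of (lon, lat) or planar (x, y) for a record list."""
    return np.array([[p.lon, p.lat] for p in items], dtype=float).reshape(-1, 2)


def households(items: Sequence[Community]) -> np.ndarray:
    return np.array([c.households for c in items], dtype=float)


def prices(items: Sequence[Community]) -> np.ndarray:
    return np.array([c.price for c in items], dtype=float)


def areas_m2(items: Sequence[GreenSpace]) -> np.ndarray:
    return np.array([g.area_m2 for g in items], dtype=float)
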