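"""Gaussian-decay two-step floating catchment area (2SFCA) accessibility.

Step 1 computes each green space's supply-to-demand ratio

    R_j = S_j / sum_{k: d_kj <= d0} G(d_kj, d0) * H_k,

where S_j is the green area (m²), H_k the households of community k and
G the truncated Gaussian kernel. Step 2 sums the ratios reachable from
each community,

    A_i = sum_{l: d_il <= d0} G(d_il, d0) * R_l,

giving accessibility in m² of green space per household. A green space
whose catchment holds no positively weighted demand has an undefined
ratio; it is flagged unused (NaN) and, because its kernel weight to any
such community is zero anyway, it cannot contribute to any A_i.

The kernel follows the standard Gaussian 2SFCA form with a squared
distance ratio,

    G(d, d0) = [exp(-(d/d0)²/2) - exp(-1/2)] / [1 - exp(-1/2)]  for d <= d0,
    G(d, d0) = 0                                                for d > d0,

which equals 1 at d = 0 and falls continuously to 0 at the catchment
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spatial import DistanceMatrix, pairwise_distances
from .types import Community, GreenSpace, areas_m2, coords, households

_HALF = np.exp(-0.5)


def gaussian_decay(d, d0: float):
    """Truncated Gaussian distance-decay weight in [0, 1].

    Accepts a scalar or array of distances; ``d0`` must be positive.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    d_arr = np.asarray(d, dtype=float)
    if (d_arr < 0).any():
        raise ValueError("distances must be nonnegative")
    g = (np.exp(-0.5 * (d_arr / d0) ** 2) - _HALF) / (1.0 - _HALF)
    g = np.where(d_arr > d0, 0.0, g)
    if np.isscalar(d):
        return float(g)
    return g


def _kernel_matrix(dmatrix: DistanceMatrix, d0: float) -> np.ndarray:
    return np.asarray(gaussian_decay(dmatrix.values, d0))


def supply_demand_ratio(
    dmatrix: DistanceMatrix,
    supply_m2: np.ndarray,
    demand_households: np.ndarray,
    d0: float,
) -> np.ndarray:
    """Per-green-space ratio R_j (m²/household); NaN where unused.

    A ratio is unused when no community carries positive kernel weight
    within the catchment — either the catchment is empty or every member
    sits exactly on the boundary, where the kernel vanishes.
    """
    supply_m2 = np.asarray(supply_m2, dtype=float)
    demand_households = np.asarray(demand_households, dtype=float)
    g = _kernel_matrix(dmatrix, d0)  # demand x supply
    denom = g.T @ demand_households  # per supply point
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, supply_m2 / denom, np.nan)
    return r


def accessibility(dmatrix: DistanceMatrix, r: np.ndarray, d0: float) -> np.ndarray:
    """Per-community accessibility A_i = sum of decay-weighted ratios."""
    g = _kernel_matrix(dmatrix, d0)
    r_filled = np.nan_to_num(np.asarray(r, dtype=float), nan=0.0)
    return g @ r_filled


@dataclass(frozen=True)
class AccessibilityField:
    """2SFCA result for one city at one catchment radius."""

    city_id: str
    d0: float
    community_ids: tuple[str, ...]
    households: np.ndarray
    A: np.ndarray  # m² green space per household, one per community
    R: np.ndarray  # per green space; NaN = unused (no weighted demand)

    @property
    def total_weighted_access(self) -> float:
        """Σ H_i · A_i — equals the total used green area (m²)."""
        return float(self.households @ self.A)


def two_step_fca(
    communities: Sequence[Community],
    greenspaces: Sequence[GreenSpace],
    d0: float,
    metric: str = "haversine",
    dmatrix: DistanceMatrix | None = None,
) -> AccessibilityField:
    """Run both 2SFCA steps for one city at one radius.

    ``dmatrix`` may be supplied to reuse distances across radii;
    otherwise it is computed with ``metric``.
    """
    if len(communities) == 0:
        raise ValueError("city has no demand points")
    city_id = communities[0].city_id
    h = households(communities)
    ids = tuple(c.id for c in communities)
    if len(greenspaces) == 0:
        warnings.warn(f"city {city_id}: no green spaces; all accessibility is 0")
        return AccessibilityField(
            city_id=city_id,
            d0=float(d0),
            community_ids=ids,
            households=h,
            A=np.zeros(len(communities)),
            R=np.array([]),
        )
    if dmatrix is None:
        dmatrix = pairwise_distances(coords(communities), coords(greenspaces), metric)
    s = areas_m2(greenspaces)
    r = supply_demand_ratio(dmatrix, s, h, d0)
    a = accessibility(dmatrix, r, d0)
    return AccessibilityField(
        city_id=city_id,
        d0=float(d0),
        community_ids=ids,
        households=h,
        A=a,
        R=r,
    )
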