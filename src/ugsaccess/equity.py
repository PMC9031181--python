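"""City-level equity of accessibility: Lorenz curve, grouped Gini, levels.

Each community is one group, weighted by its households. The Gini
coefficient is computed from the grouped formula

    GC = Σ p_i y_i  −  2 Σ (ΣP_i)' y_i  +  1,

with p_i the household share of group i, y_i the group's share of total
accessibility mass (H_i·A_i / ΣH·A) and (ΣP_i)' the cumulative
household share, groups ordered by *descending* per-household
accessibility — the ordering under which the formula returns the
nonnegative statistic that equals the classical weighted
mean-absolute-difference Gini. Cities whose total accessibility is zero
(no green space in reach of any community) carry no Gini and are
excluded from equity reporting, as are cities with fewer groups than a
configurable minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fca import AccessibilityField

LEVELS = ("Good", "Normal", "Warning", "Dangerous")


@dataclass(frozen=True)
class LorenzCurve:
    """Cumulative household share (x) vs cumulative accessibility share (y)."""

    x: np.ndarray
    y: np.ndarray


@dataclass(frozen=True)
class GiniResult:
    city_id: str
    d0: float
    gini: float | None
    level: str | None
    n_groups: int
    excluded: bool = False
    reason: str | None = None


class DegenerateCityError(ValueError):
    """Raised when total accessibility is zero and no Gini is defined."""


def _validate(households: np.ndarray, access: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h = np.asarray(households, dtype=float)
    a = np.asarray(access, dtype=float)
    if h.shape != a.shape or h.ndim != 1:
        raise ValueError("households and access must be equal-length 1-d arrays")
    if (h <= 0).any():
        raise ValueError("household weights must be positive")
    if (a < 0).any():
        raise ValueError("accessibility values must be nonnegative")
    if h.sum() <= 0:
        raise ValueError("total households must be positive")
    if (h * a).sum() == 0:
        raise DegenerateCityError("total accessibility is zero")
    return h, a


def lorenz(households: np.ndarray, access: np.ndarray) -> LorenzCurve:
    """Lorenz curve of per-household accessibility across groups.

    Groups are sorted ascending by accessibility per household; both
    coordinates run from 0 to 1 inclusive.
    """
    h, a = _validate(households, access)
    order = np.argsort(a, kind="stable")
    h, a = h[order], a[order]
    mass = h * a
    x = np.concatenate([[0.0], np.cumsum(h) / h.sum()])
    y = np.concatenate([[0.0], np.cumsum(mass) / mass.sum()])
    return LorenzCurve(x=x, y=y)


def gini_grouped(households: np.ndarray, access: np.ndarray) -> float:
    """Household-weighted Gini coefficient of per-household accessibility."""
    h, a = _validate(households, access)
    order = np.argsort(-a, kind="stable")  # descending
    h, a = h[order], a[order]
    p = h / h.sum()
    mass = h * a
    y = mass / mass.sum()
    cum_p = np.cumsum(p)
    gc = float((p * y).sum() - 2.0 * (cum_p * y).sum() + 1.0)
    # perfect equality yields 0 up to rounding; keep the result in [0, 1)
    return 0.0 if -1e-12 < gc < 0.0 else gc


def classify_inequality(gini: float) -> str:
    """Map a Gini value to its inequality level.

    Good: [0, 0.3); Normal: [0.3, 0.4); Warning: [0.4, 0.6];
    Dangerous: (0.6, 1). Values at exactly 0.6 fall in Warning because
    Dangerous is the strictly-greater band.
    """
    if not (0.0 <= gini < 1.0):
        raise ValueError(f"gini {gini} outside [0, 1)")
    if gini < 0.3:
        return "Good"
    if gini < 0.4:
        return "Normal"
    if gini <= 0.6:
        return "Warning"
    return "Dangerous"


def exclude_city(
    field: AccessibilityField, min_communities: int = 2
) -> tuple[bool, str | None]:
    """Decide whether a city enters Gini reporting.

    Returns ``(excluded, reason)``. Cities where no community reaches
    any green space (total accessibility zero) are excluded, as are
    cities with fewer communities than ``min_communities`` — a Gini
    over a single group is vacuous.
    """
    if len(field.community_ids) < min_communities:
        return True, "insufficient groups"
    if float(field.households @ field.A) == 0.0:
        return True, "zero accessibility"
    return False, None


def city_gini(field: AccessibilityField, min_communities: int = 2) -> GiniResult:
    """Gini of one city's accessibility field, applying the exclusion rule."""
    excluded, reason = exclude_city(field, min_communities)
    if excluded:
        return GiniResult(
            city_id=field.city_id,
            d0=field.d0,
            gini=None,
            level=None,
            n_groups=len(field.community_ids),
            excluded=True,
            reason=reason,
        )
    g = gini_grouped(field.households, field.A)
    return GiniResult(
        city_id=field.city_id,
        d0=field.d0,
        gini=g,
        level=classify_inequality(g),
        n_groups=len(field.community_ids),
    )
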