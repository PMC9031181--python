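"""Comparative analyses: traditional accessibility, ratio, t-tests, tier OLS.

The "traditional" accessibility baseline considers supply but not
demand: it sums the decay-weighted green area reachable from a
community and (in the default variant) divides by that community's own
households, so it shares units with 2SFCA accessibility but ignores
competition from other communities. The city-level ratio of mean 2SFCA
to mean traditional accessibility exceeds 1 where the demand-blind
method underestimates real access.

City attributes of the ratio>1 and ratio<1 groups are compared with a
Welch (unequal-variance) two-sided t-test, and the relationship between
mean house price and the Gini of accessibility is fit per price tier by
ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm

from .fca import AccessibilityField, _kernel_matrix
from .spatial import DistanceMatrix


@dataclass(frozen=True)
class CitySummary:
    city_id: str
    d0: float
    mean_A: float  # unweighted mean over communities
    mean_A_weighted: float  # household-weighted mean
    mean_A_traditional: float
    ratio: float | None  # None when the traditional mean is zero
    total_green_ha: float
    mean_price: float


@dataclass(frozen=True)
class TTestResult:
    indicator: str
    mean_a: float
    mean_b: float
    t: float
    p: float
    n_a: int
    n_b: int

    @property
    def stars(self) -> str:
        """Significance stars at the 0.10 / 0.05 / 0.01 levels."""
        if self.p < 0.01:
            return "***"
        if self.p < 0.05:
            return "**"
        if self.p < 0.10:
            return "*"
        return ""


@dataclass(frozen=True)
class TierRegression:
    tier: int
    lower: float
    upper: float
    d0: float
    slope: float | None
    intercept: float | None
    p_value: float | None
    n: int
    degenerate: bool = False

    @property
    def stars(self) -> str:
        if self.p_value is None:
            return ""
        if self.p_value < 0.01:
            return "***"
        if self.p_value < 0.05:
            return "**"
        if self.p_value < 0.10:
            return "*"
        return ""


def traditional_accessibility(
    dmatrix: DistanceMatrix,
    supply_m2: np.ndarray,
    demand_households: np.ndarray,
    d0: float,
    variant: str = "per_household",
) -> np.ndarray:
    """Demand-blind accessibility per community.

    ``per_household`` (default): Σ_{l reachable} S_l / H_i — the
    green area within reach divided by the community's own households.
    This is 2SFCA with cross-community demand competition removed: each
    spot's ratio is taken as if the community were its only user, in
    which case the kernel weight cancels, so with a single community
    per supply cluster it coincides exactly with 2SFCA. A spot exactly
    on the catchment boundary carries kernel weight zero and therefore
    does not count as reachable.

    ``decayed_per_household``: Σ_l G(d_il, d0)·S_l / H_i — decayed
    reachable supply per own household (keeps the kernel, so it no
    longer coincides with 2SFCA for an isolated community).
    ``decayed_supply``: Σ_l G(d_il, d0)·S_l, no normalization.
    """
    g = _kernel_matrix(dmatrix, d0)
    supply_m2 = np.asarray(supply_m2, dtype=float)
    if variant == "per_household":
        reachable = (g > 0).astype(float) @ supply_m2
        return reachable / np.asarray(demand_households, dtype=float)
    if variant == "decayed_per_household":
        return (g @ supply_m2) / np.asarray(demand_households, dtype=float)
    if variant == "decayed_supply":
        return g @ supply_m2
    raise ValueError(f"unknown traditional variant {variant!r}")


def city_ratio(
    field: AccessibilityField,
    a_traditional: np.ndarray,
    total_green_ha: float = float("nan"),
    mean_price: float = float("nan"),
    weighted: bool = False,
) -> CitySummary:
    """Summarize one city: mean accessibilities and their 2SFCA/traditional ratio.

    The ratio uses unweighted community means by default (the average
    community accessibility level); household-weighted means are also
    reported.
    """
    a_traditional = np.asarray(a_traditional, dtype=float)
    if a_traditional.shape != field.A.shape:
        raise ValueError("fields cover different communities")
    h = field.households
    mean_a = float(field.A.mean())
    mean_a_w = float((h @ field.A) / h.sum())
    mean_trad = float(
        (h @ a_traditional) / h.sum() if weighted else a_traditional.mean()
    )
    numerator = mean_a_w if weighted else mean_a
    ratio = numerator / mean_trad if mean_trad > 0 else None
    return CitySummary(
        city_id=field.city_id,
        d0=field.d0,
        mean_A=mean_a,
        mean_A_weighted=mean_a_w,
        mean_A_traditional=mean_trad,
        ratio=ratio,
        total_green_ha=total_green_ha,
        mean_price=mean_price,
    )


def welch_t_test(values_a, values_b, indicator: str = "") -> TTestResult:
    """Two-sided Welch t-test comparing one indicator across two city groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        indicator=indicator,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(t),
        p=float(p),
        n_a=len(a),
        n_b=len(b),
    )


def price_tiers(
    city_prices, breakpoints=None, quantile: bool = False, n_tiers: int = 5
) -> np.ndarray:
    """Assign each city a 0-based price tier.

    With fixed ``breakpoints`` (interior edges, ascending), a price
    equal to an edge goes to the lower tier — bands are contiguous
    closed intervals (…–5500, 5501–…). ``quantile=True`` instead cuts
    at the empirical quantiles into ``n_tiers`` near-equal groups,
    which suits synthetic prices on a different scale.
    """
    prices_arr = np.asarray(city_prices, dtype=float)
    if quantile:
        qs = np.quantile(prices_arr, np.linspace(0, 1, n_tiers + 1)[1:-1])
        return np.searchsorted(qs, prices_arr, side="left").astype(int)
    from .types import DEFAULT_PRICE_BREAKPOINTS

    bp = np.asarray(
        DEFAULT_PRICE_BREAKPOINTS if breakpoints is None else breakpoints, dtype=float
    )
    if (np.diff(bp) <= 0).any():
        raise ValueError("breakpoints must be strictly ascending")
    # side="left": price == edge lands in the lower tier
    return np.searchsorted(bp, prices_arr, side="left").astype(int)


def tier_ols(
    gini_by_city,
    price_by_city,
    tiers,
    d0: float,
    breakpoints=None,
    min_n: int = 3,
) -> list[TierRegression]:
    """Per-tier OLS of Gini on mean house price at one radius.

    Tiers with fewer than ``min_n`` cities, or with constant price, are
    reported as degenerate without a fit.
    """
    gini_arr = np.asarray(gini_by_city, dtype=float)
    price_arr = np.asarray(price_by_city, dtype=float)
    tier_arr = np.asarray(tiers, dtype=int)
    from .types import DEFAULT_PRICE_BREAKPOINTS

    bp = list(DEFAULT_PRICE_BREAKPOINTS if breakpoints is None else breakpoints)
    edges = [-np.inf] + bp + [np.inf]
    out: list[TierRegression] = []
    for t in range(len(edges) - 1):
        mask = tier_arr == t
        n = int(mask.sum())
        lower, upper = float(edges[t]), float(edges[t + 1])
        if n < min_n or np.ptp(price_arr[mask]) == 0:
            out.append(
                TierRegression(t, lower, upper, d0, None, None, None, n, degenerate=True)
            )
            continue
        x = sm.add_constant(price_arr[mask])
        fit = sm.OLS(gini_arr[mask], x).fit()
        out.append(
            TierRegression(
                tier=t,
                lower=lower,
                upper=upper,
                d0=d0,
                slope=float(fit.params[1]),
                intercept=float(fit.params[0]),
                p_value=float(fit.pvalues[1]),
                n=n,
            )
        )
    return out
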