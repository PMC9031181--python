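"""Synthetic multi-city point data with controllable spatial structure.

Real inputs for this kind of analysis — crawled community listings and
green-space map spots — are not openly deposited, so the package ships
a generator that emulates their published marginals: about 33 green
spots and 315 communities per city on average, lognormal spot areas
with mean 14.96 ha truncated at 1 ha, and house prices around
16,368 yuan/m². Spatial structure is controllable: community layout
(uniform, monocentric, clustered), concentration of green spots near a
focus (``green_cluster``), and a price–green coupling γ that makes
house prices rise with decay-weighted green proximity, emulating the
willingness to pay a premium for living near parks.

Coordinates are planar meters inside a square of side ``extent_m``
(analyses on generated data should use the Euclidean metric).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .fca import gaussian_decay
from .spatial import euclidean_matrix
from .types import Community, GreenSpace

#: Published per-city marginals the generator targets (means only).
MEAN_GREENSPOTS = 33.06
MEAN_SPOT_AREA_HA = 14.96
MEAN_COMMUNITIES = 315.06
MEAN_PRICE = 16_367.76


@dataclass(frozen=True)
class SyntheticCityConfig:
    """Generative parameters for one city.

    ``n_communities`` / ``n_greenspots`` fix the counts; when ``None``
    they are drawn Poisson around the published per-city means.
    ``green_cluster`` = 0 places spots uniformly; larger values
    concentrate them near a focus point. ``price_green_coupling`` (γ)
    scales the log-price premium per standard deviation of
    decay-weighted green proximity; ``price_noise_sd`` is the residual
    log-price noise.
    """

    n_communities: int | None = None
    n_greenspots: int | None = None
    mean_communities: float = MEAN_COMMUNITIES
    mean_greenspots: float = MEAN_GREENSPOTS
    extent_m: float = 20_000.0
    layout: str = "uniform"  # uniform | monocentric | clustered
    green_cluster: float = 0.0
    spot_area_mean_ha: float = MEAN_SPOT_AREA_HA
    spot_area_sigma: float = 1.2  # lognormal shape parameter
    households_median: float = 800.0
    households_sigma: float = 0.8
    price_base: float = MEAN_PRICE
    price_green_coupling: float = 0.0
    price_noise_sd: float = 0.15
    proximity_radius_m: float = 2_500.0  # radius defining "green proximity"

    def __post_init__(self) -> None:
        if self.extent_m <= 0:
            raise ValueError("extent must be positive")
        if self.layout not in ("uniform", "monocentric", "clustered"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.green_cluster < 0:
            raise ValueError("green_cluster must be nonnegative")
        for name in (
            "mean_communities",
            "mean_greenspots",
            "spot_area_mean_ha",
            "spot_area_sigma",
            "households_median",
            "households_sigma",
            "price_base",
            "proximity_radius_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n = self.n_communities if self.n_communities is not None else self.mean_communities
        # ~100 m² per point is a loose feasibility floor for distinct placement
        if self.extent_m**2 < 100.0 * n:
            raise ValueError("extent too small for the requested point count")


def _positive_poisson(rng: np.random.Generator, mean: float) -> int:
    return int(max(1, rng.poisson(mean)))


def _place(
    rng: np.random.Generator, n: int, extent: float, layout: str
) -> np.ndarray:
    center = np.array([extent / 2.0, extent / 2.0])
    if layout == "uniform":
        return rng.uniform(0.0, extent, size=(n, 2))
    if layout == "monocentric":
        pts = center + rng.normal(0.0, extent / 6.0, size=(n, 2))
        return np.clip(pts, 0.0, extent)
    # clustered: a handful of Gaussian sub-centers
    k = max(2, int(np.sqrt(n) / 3))
    centers = rng.uniform(0.15 * extent, 0.85 * extent, size=(k, 2))
    which = rng.integers(0, k, size=n)
    pts = centers[which] + rng.normal(0.0, extent / 12.0, size=(n, 2))
    return np.clip(pts, 0.0, extent)


def _place_green(
    rng: np.random.Generator, n: int, extent: float, concentration: float
) -> np.ndarray:
    if concentration == 0.0:
        return rng.uniform(0.0, extent, size=(n, 2))
    focus = rng.uniform(0.25 * extent, 0.75 * extent, size=2)
    sd = extent / (2.0 * (1.0 + concentration))
    return np.clip(focus + rng.normal(0.0, sd, size=(n, 2)), 0.0, extent)


def _truncated_lognormal_areas(
    rng: np.random.Generator, n: int, mean_ha: float, sigma: float
) -> np.ndarray:
    """Lognormal areas (m²) with target mean, resampled to stay >= 1 ha."""
    mu = np.log(mean_ha) - sigma**2 / 2.0
    areas = rng.lognormal(mu, sigma, size=n)
    for _ in range(100):
        low = areas < 1.0
        if not low.any():
            break
        areas[low] = rng.lognormal(mu, sigma, size=int(low.sum()))
    return np.maximum(areas, 1.0) * 10_000.0


def generate_city(
    config: SyntheticCityConfig,
    seed: int | np.random.Generator | None = 0,
    city_id: str = "city",
) -> tuple[list[Community], list[GreenSpace]]:
    """Generate one synthetic city; reproducible for a fixed seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_com = (
        config.n_communities
        if config.n_communities is not None
        else _positive_poisson(rng, config.mean_communities)
    )
    n_green = (
        config.n_greenspots
        if config.n_greenspots is not None
        else _positive_poisson(rng, config.mean_greenspots)
    )
    com_xy = _place(rng, n_com, config.extent_m, config.layout)
    green_xy = _place_green(rng, n_green, config.extent_m, config.green_cluster)
    areas = _truncated_lognormal_areas(
        rng, n_green, config.spot_area_mean_ha, config.spot_area_sigma
    )
    hh = np.maximum(
        1,
        np.round(
            rng.lognormal(np.log(config.households_median), config.households_sigma, n_com)
        ),
    ).astype(int)

    # decay-weighted green proximity drives the price premium
    d = euclidean_matrix(com_xy, green_xy)
    g = np.asarray(gaussian_decay(d, config.proximity_radius_m))
    prox = g @ areas
    sd = prox.std()
    z = (prox - prox.mean()) / sd if sd > 0 else np.zeros(n_com)
    noise = rng.normal(0.0, config.price_noise_sd, n_com)
    price = config.price_base * np.exp(config.price_green_coupling * z + noise)

    communities = [
        Community(
            id=f"{city_id}-c{i:04d}",
            lon=float(com_xy[i, 0]),
            lat=float(com_xy[i, 1]),
            households=int(hh[i]),
            price=float(price[i]),
            city_id=city_id,
        )
        for i in range(n_com)
    ]
    greenspaces = [
        GreenSpace(
            id=f"{city_id}-g{j:04d}",
            lon=float(green_xy[j, 0]),
            lat=float(green_xy[j, 1]),
            area_m2=float(areas[j]),
            city_id=city_id,
        )
        for j in range(n_green)
    ]
    return communities, greenspaces


def generate_country(
    n_cities: int,
    template: SyntheticCityConfig | None = None,
    seed: int = 0,
    degenerate_prob: float = 0.0,
    jitter: float = 0.2,
) -> tuple[list[Community], list[GreenSpace], list[str]]:
    """Generate a multi-city dataset with heterogeneous city parameters.

    Per-city means are jittered lognormally around the template (scale
    ``jitter``). With probability ``degenerate_prob`` a city is made
    degenerate — its green spots are translated far beyond any
    catchment radius of its communities — to exercise the
    zero-accessibility exclusion rule. Returns the pooled communities,
    green spaces, and the ids of the cities constructed as degenerate.
    """
    if n_cities < 1:
        raise ValueError("n_cities must be >= 1")
    template = template or SyntheticCityConfig()
    root = np.random.default_rng(seed)
    communities: list[Community] = []
    greenspaces: list[GreenSpace] = []
    degenerate_ids: list[str] = []
    for c in range(n_cities):
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        cfg = replace(
            template,
            mean_communities=template.mean_communities * rng.lognormal(0, jitter),
            mean_greenspots=template.mean_greenspots * rng.lognormal(0, jitter),
            price_base=template.price_base * rng.lognormal(0, jitter),
            spot_area_mean_ha=template.spot_area_mean_ha * rng.lognormal(0, jitter),
        )
        city_id = f"city_{c:03d}"
        coms, greens = generate_city(cfg, rng, city_id=city_id)
        if rng.random() < degenerate_prob:
            # push all supply out of reach of every community at any radius
            offset = cfg.extent_m + 50_000.0
            greens = [
                GreenSpace(g.id, g.lon + offset, g.lat + offset, g.area_m2, g.city_id)
                for g in greens
            ]
            degenerate_ids.append(city_id)
        communities.extend(coms)
        greenspaces.extend(greens)
    return communities, greenspaces, degenerate_ids


def inequality_scenario(
    level: str, seed: int = 0, d0: float = 1_000.0
) -> tuple[list[Community], list[GreenSpace]]:
    """Fixture cities with known equity structure.

    ``equal``: identical, mutually unreachable spot–community pairs —
    per-household accessibility is the same everywhere (Gini 0).
    ``clustered``: communities spread over the city but all green space
    packed into one corner quadrant — high inequality.
    ``extreme``: two equal-household communities with every green space
    adjacent to the first and out of reach of the second — the
    two-group analytic case (Gini 0.5).
    """
    rng = np.random.default_rng(seed)
    spacing = 10.0 * d0
    if level == "equal":
        k = 5
        communities = [
            Community(f"eq-c{i}", i * spacing, 0.0, 100, 10_000.0, "equal")
            for i in range(k)
        ]
        greens = [
            GreenSpace(f"eq-g{i}", i * spacing, 0.0, 50_000.0, "equal")
            for i in range(k)
        ]
        return communities, greens
    if level == "extreme":
        communities = [
            Community("ex-c0", 0.0, 0.0, 100, 10_000.0, "extreme"),
            Community("ex-c1", spacing, 0.0, 100, 10_000.0, "extreme"),
        ]
        greens = [GreenSpace("ex-g0", 0.0, 0.0, 50_000.0, "extreme")]
        return communities, greens
    if level == "clustered":
        extent = 10.0 * d0
        n_com, n_green = 60, 12
        com_xy = rng.uniform(0.0, extent, size=(n_com, 2))
        green_xy = rng.uniform(0.0, 0.25 * extent, size=(n_green, 2))
        areas = _truncated_lognormal_areas(rng, n_green, MEAN_SPOT_AREA_HA, 1.2)
        hh = np.maximum(1, rng.poisson(500, n_com))
        communities = [
            Community(
                f"cl-c{i}", float(com_xy[i, 0]), float(com_xy[i, 1]),
                int(hh[i]), 10_000.0, "clustered",
            )
            for i in range(n_com)
        ]
        greens = [
            GreenSpace(
                f"cl-g{j}", float(green_xy[j, 0]), float(green_xy[j, 1]),
                float(areas[j]), "clustered",
            )
            for j in range(n_green)
        ]
        return communities, greens
    raise ValueError(f"unknown scenario {level!r}")
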