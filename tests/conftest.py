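import math

import numpy as np
import pytest

from ugsaccess import Community, GreenSpace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_community(i, x, y, households=100, price=10_000.0, city="city"):
    return Community(f"c{i}", x, y, households, price, city)


def make_green(j, x, y, area_m2=50_000.0, city="city"):
    return GreenSpace(f"g{j}", x, y, area_m2, city)


def random_instance(rng, max_com=200, max_green=50, extent=20_000.0):
    """Random planar city: coordinates, households, green areas."""
    n = int(rng.integers(1, max_com + 1))
    m = int(rng.integers(1, max_green + 1))
    coms = [
        make_community(
            i,
            float(rng.uniform(0, extent)),
            float(rng.uniform(0, extent)),
            int(rng.integers(1, 2000)),
        )
        for i in range(n)
    ]
    greens = [
        make_green(
            j,
            float(rng.uniform(0, extent)),
            float(rng.uniform(0, extent)),
            float(rng.lognormal(np.log(150_000), 1.0)),
        )
        for j in range(m)
    ]
    return coms, greens


def gaussian_reference(d, d0):
    """Scalar truncated-Gaussian kernel, written independently."""
    if d > d0:
        return 0.0
    return (math.exp(-0.5 * (d / d0) ** 2) - math.exp(-0.5)) / (1.0 - math.exp(-0.5))


def fca_reference(coms, greens, d0):
    """Literal double-loop transcription of the three 2SFCA steps (planar)."""
    def dist(a, b):
        return math.hypot(a.lon - b.lon, a.lat - b.lat)

    R = []
    for g in greens:
        denom = 0.0
        for c in coms:
            d = dist(c, g)
            if d <= d0:
                denom += gaussian_reference(d, d0) * c.households
        R.append(g.area_m2 / denom if denom > 0 else None)
    A = []
    for c in coms:
        a = 0.0
        for g, r in zip(greens, R):
            d = dist(c, g)
            if d <= d0 and r is not None:
                a += gaussian_reference(d, d0) * r
        A.append(a)
    return np.array(A), R


def gini_pairwise_reference(households, values):
    """Weighted mean-absolute-difference Gini, the brute-force oracle."""
    h = np.asarray(households, float)
    x = np.asarray(values, float)
    w_total = h.sum()
    mu = (h * x).sum() / w_total
    num = 0.0
    for i in range(len(x)):
        for j in range(len(x)):
            num += h[i] * h[j] * abs(x[i] - x[j])
    return num / (2.0 * w_total**2 * mu)
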