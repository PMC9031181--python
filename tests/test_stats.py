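import numpy as np
import pytest

from ugsaccess import (
    GreenSpace,
    city_ratio,
    price_tiers,
    tier_ols,
    traditional_accessibility,
    two_step_fca,
    welch_t_test,
)
from ugsaccess.spatial import DistanceMatrix, pairwise_distances
from ugsaccess.types import areas_m2, coords, households

from conftest import make_community, make_green, random_instance


class TestTraditionalAccessibility:
    def test_single_community_coincides_with_2sfca(self):
        coms = [make_community(0, 0, 0, households=100)]
        greens = [make_green(0, 0, 0, area_m2=10_000.0)]
        dm = pairwise_distances(coords(coms), coords(greens), "euclidean")
        a_trad = traditional_accessibility(dm, areas_m2(greens), households(coms), 1_000.0)
        f = two_step_fca(coms, greens, 1_000.0, metric="euclidean")
        assert a_trad[0] == pytest.approx(100.0)
        assert f.A[0] == pytest.approx(100.0)

    def test_competition_halves_2sfca_only(self):
        coms = [make_community(i, 0, 0, households=100) for i in range(2)]
        greens = [make_green(0, 0, 0, area_m2=10_000.0)]
        dm = pairwise_distances(coords(coms), coords(greens), "euclidean")
        a_trad = traditional_accessibility(dm, areas_m2(greens), households(coms), 1_000.0)
        f = two_step_fca(coms, greens, 1_000.0, metric="euclidean")
        assert np.allclose(a_trad, [100.0, 100.0])
        assert np.allclose(f.A, [50.0, 50.0])
        summary = city_ratio(f, a_trad)
        assert summary.ratio == pytest.approx(0.5)

    def test_out_of_range_supply_gives_zero(self):
        dm = DistanceMatrix(np.array([[99_999.0]]), "euclidean")
        a = traditional_accessibility(dm, np.array([1e5]), np.array([10.0]), 1_000.0)
        assert a[0] == 0.0

    def test_variant_family(self):
        # one spot at half the radius: kernel weight ~0.7013666
        dm = DistanceMatrix(np.array([[500.0]]), "euclidean")
        s, h = np.array([5e4]), np.array([200.0])
        own = traditional_accessibility(dm, s, h, 1_000.0)
        decayed = traditional_accessibility(
            dm, s, h, 1_000.0, variant="decayed_per_household"
        )
        raw = traditional_accessibility(dm, s, h, 1_000.0, variant="decayed_supply")
        from ugsaccess import gaussian_decay

        g = gaussian_decay(500.0, 1_000.0)
        assert own[0] == pytest.approx(250.0)
        assert decayed[0] == pytest.approx(g * 250.0)
        assert raw[0] == pytest.approx(g * 5e4)
        with pytest.raises(ValueError):
            traditional_accessibility(dm, s, h, 1_000.0, variant="nope")

    def test_boundary_spot_not_reachable(self):
        # kernel weight is zero at exactly d0, so the spot contributes nothing
        dm = DistanceMatrix(np.array([[1_000.0]]), "euclidean")
        own = traditional_accessibility(dm, np.array([5e4]), np.array([200.0]), 1_000.0)
        assert own[0] == 0.0

    def test_identity_on_random_single_community_instances(self, rng):
        # with one community, the competition term is the community itself
        for _ in range(50):
            coms = [
                make_community(
                    0,
                    float(rng.uniform(0, 5_000)),
                    float(rng.uniform(0, 5_000)),
                    int(rng.integers(1, 2000)),
                )
            ]
            greens = [
                make_green(
                    j,
                    float(rng.uniform(0, 5_000)),
                    float(rng.uniform(0, 5_000)),
                    float(rng.lognormal(np.log(1e5), 1.0)),
                )
                for j in range(int(rng.integers(1, 10)))
            ]
            d0 = float(rng.choice([1_000.0, 2_500.0, 5_000.0]))
            dm = pairwise_distances(coords(coms), coords(greens), "euclidean")
            a_trad = traditional_accessibility(dm, areas_m2(greens), households(coms), d0)
            f = two_step_fca(coms, greens, d0, metric="euclidean", dmatrix=dm)
            assert f.A[0] == pytest.approx(a_trad[0], rel=1e-9, abs=1e-12)

    def test_ratio_invariant_to_uniform_supply_scaling(self, rng):
        coms, greens = random_instance(rng, max_com=40, max_green=10)
        d0 = 5_000.0
        dm = pairwise_distances(coords(coms), coords(greens), "euclidean")
        f = two_step_fca(coms, greens, d0, metric="euclidean", dmatrix=dm)
        at = traditional_accessibility(dm, areas_m2(greens), households(coms), d0)
        s1 = city_ratio(f, at)
        scaled = [GreenSpace(g.id, g.lon, g.lat, 7.0 * g.area_m2, g.city_id) for g in greens]
        f2 = two_step_fca(coms, scaled, d0, metric="euclidean", dmatrix=dm)
        at2 = traditional_accessibility(dm, areas_m2(scaled), households(coms), d0)
        s2 = city_ratio(f2, at2)
        if s1.ratio is not None:
            assert s2.ratio == pytest.approx(s1.ratio, rel=1e-9)


class TestCityRatio:
    def test_identical_fields_ratio_one(self):
        coms = [make_community(i, i * 10.0, 0, households=50) for i in range(3)]
        greens = [make_green(0, 0, 0)]
        f = two_step_fca(coms, greens, 1_000.0, metric="euclidean")
        s = city_ratio(f, f.A.copy())
        assert s.ratio == pytest.approx(1.0)

    def test_zero_traditional_flagged(self):
        coms = [make_community(0, 0, 0), make_community(1, 10, 0)]
        greens = [make_green(0, 1e6, 0)]
        f = two_step_fca(coms, greens, 1_000.0, metric="euclidean")
        s = city_ratio(f, np.zeros(2))
        assert s.ratio is None

    def test_zero_fca_positive_traditional(self):
        coms = [make_community(0, 0, 0), make_community(1, 10, 0)]
        greens = [make_green(0, 1e6, 0)]
        f = two_step_fca(coms, greens, 1_000.0, metric="euclidean")
        s = city_ratio(f, np.array([5.0, 5.0]))
        assert s.ratio == pytest.approx(0.0)


class TestWelchTTest:
    def test_identical_groups(self):
        r = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_shifted_groups_significant(self):
        r = welch_t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert r.p < 0.01
        assert r.t < 0

    def test_symmetry(self):
        a, b = [1.0, 2.0, 5.0], [4.0, 9.0, 11.0]
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [2.0, 3.0])

    def test_stars(self):
        assert welch_t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0]).stars == "***"
        assert welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).stars == ""


class TestPriceTiers:
    def test_published_band_examples(self):
        tiers = price_tiers([6_000.0, 5_500.0, 5_501.0, 30_000.0, 500.0])
        # 6000 -> band 5501-7640; 5500 -> band 500-5500 (edge goes low)
        assert tiers.tolist() == [1, 0, 1, 4, 0]

    def test_all_edges_go_to_lower_tier(self):
        edges = [5_500.0, 7_640.0, 11_038.0, 23_902.0]
        assert price_tiers(edges).tolist() == [0, 1, 2, 3]

    def test_quantile_mode_balanced(self):
        prices = np.arange(10, dtype=float) * 1_000 + 1_000
        tiers = price_tiers(prices, quantile=True)
        counts = np.bincount(tiers, minlength=5)
        assert counts.tolist() == [2, 2, 2, 2, 2]

    def test_bad_breakpoints(self):
        with pytest.raises(ValueError):
            price_tiers([1.0], breakpoints=[5.0, 3.0])


class TestTierOLS:
    def test_exact_line_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = 2.0 * x + 1.0
        regs = tier_ols(y, x, np.zeros(5, int), 1_000.0, breakpoints=[10.0])
        r = regs[0]
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)

    def test_constant_y_zero_slope(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        regs = tier_ols(np.full(4, 0.4), x, np.zeros(4, int), 1_000.0, breakpoints=[10.0])
        assert regs[0].slope == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_normal_equations(self):
        x = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
        y = np.array([0.31, 0.42, 0.38, 0.55, 0.61])
        slope_cf = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        regs = tier_ols(y, x, np.zeros(5, int), 1_000.0, breakpoints=[100.0])
        assert regs[0].slope == pytest.approx(slope_cf, rel=1e-12)

    def test_slope_equivariance_under_x_scaling(self):
        x = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
        y = np.array([0.31, 0.42, 0.38, 0.55, 0.61])
        r1 = tier_ols(y, x, np.zeros(5, int), 1_000.0, breakpoints=[100.0])[0]
        r2 = tier_ols(y, 10 * x, np.zeros(5, int), 1_000.0, breakpoints=[1_000.0])[0]
        assert r2.slope == pytest.approx(r1.slope / 10.0, rel=1e-9)

    def test_small_or_degenerate_tiers_flagged(self):
        regs = tier_ols(
            [0.1, 0.2, 0.3], [1.0, 1.0, 1.0], [0, 0, 0], 1_000.0, breakpoints=[10.0]
        )
        assert regs[0].degenerate and regs[0].slope is None
        regs2 = tier_ols([0.1, 0.2], [1.0, 2.0], [0, 0], 1_000.0, breakpoints=[10.0])
        assert regs2[0].degenerate  # n < 3
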