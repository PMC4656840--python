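"""Voronoi entropy, stripe G-test, Monte Carlo nulls and Holm adjustment."""

import math

import numpy as np
import pytest
from scipy import stats
from shapely import affinity
from shapely.geometry import Polygon
from statsmodels.stats.multitest import multipletests

from fosmap.spatial import (
    SectionPattern,
    entropy_from_areas,
    gtest_uniform,
    holm_adjust,
    lateral_distance,
    mc_entropy_test,
    median_lateralization_test,
    stripe_partition,
    StripePartition,
    voronoi_entropy,
)
from fosmap.synthetic import SectionParams, make_section
from tests.conftest import SMALL_GEOMETRY


class TestVoronoiEntropy:
    def test_single_point_has_zero_entropy(self, unit_square):
        assert voronoi_entropy(np.array([[0.4, 0.6]]), unit_square) == 0.0

    def test_quadrant_centers_reach_maximum_entropy(self, unit_square):
        pts = np.array([[0.25, 0.25], [0.75, 0.25], [0.75, 0.75], [0.25, 0.75]])
        assert voronoi_entropy(pts, unit_square) == pytest.approx(math.log(4))

    def test_area_vector_formula(self):
        # direct evaluation on areas {1, 1, 2}
        assert entropy_from_areas(np.array([1.0, 1.0, 2.0])) == pytest.approx(
            1.0397, abs=1e-4
        )

    def test_entropy_bounded_by_log_n(self, small_section):
        pts = small_section.coords("cfos")
        h = voronoi_entropy(pts, small_section.region)
        assert 0 < h <= math.log(len(pts))

    def test_rigid_motion_invariance(self, small_section):
        pts = small_section.coords("cfos")
        h0 = voronoi_entropy(pts, small_section.region)
        region2 = affinity.rotate(
            affinity.translate(small_section.region, 123.0, -45.0),
            30.0,
            origin=(0, 0),
        )
        c, s = math.cos(math.radians(30)), math.sin(math.radians(30))
        rot = np.array([[c, -s], [s, c]])
        pts2 = (pts + np.array([123.0, -45.0])) @ rot.T
        h1 = voronoi_entropy(pts2, region2)
        assert h1 == pytest.approx(h0, rel=1e-6)


class TestMcEntropyTest:
    def test_reproducible_given_seed(self, small_section):
        r1 = mc_entropy_test(small_section, N_sim=200, seed=42)
        r2 = mc_entropy_test(small_section, N_sim=200, seed=42)
        assert r1.n_below == r2.n_below and r1.H_obs == r2.H_obs

    def test_clustered_pattern_rejected(self):
        # activated cells confined to a small lateral pocket
        sec = make_section(
            SectionParams(**SMALL_GEOMETRY, lateral_bias_scale=8.0), seed=5
        )
        res = mc_entropy_test(sec, N_sim=500, seed=0)
        assert res.p_value < 0.01

    def test_degenerate_full_subsample(self, unit_square, rng):
        pts = rng.uniform(0.1, 0.9, size=(12, 2))
        import pandas as pd

        df = pd.DataFrame(
            {
                "x_um": pts[:, 0],
                "y_um": pts[:, 1],
                "neun": True,
                "cfos": True,
                "gad": False,
            }
        )
        sec = SectionPattern(
            "s", "r", "contra", unit_square,
            np.array([[0.0, 0.0], [0.0, 1.0]]), df,
        )
        res = mc_entropy_test(sec, N_sim=50, seed=0)
        assert res.n_below == 0
        assert res.degenerate
        assert res.p_label.startswith("<")

    def test_activated_set_is_the_double_positive_subset(self, unit_square, rng):
        import pandas as pd

        pts = rng.uniform(0.1, 0.9, size=(8, 2))
        df = pd.DataFrame(
            {
                "x_um": pts[:, 0],
                "y_um": pts[:, 1],
                "neun": [True] * 4 + [False] * 4,
                "cfos": True,
                "gad": False,
            }
        )
        sec = SectionPattern(
            "s", "r", "contra", unit_square,
            np.array([[0.0, 0.0], [0.0, 1.0]]), df,
        )
        # only NeuN/c-Fos double positives count as activated (4 of 8 here),
        # so the subsample covers the whole NeuN set: degenerate, p bounded
        res = mc_entropy_test(sec, N_sim=20, seed=0)
        assert res.n_cfos == 4
        assert res.degenerate and res.n_below == 0


class TestStripesAndGTest:
    def _square_section(self, xs, ys):
        import pandas as pd

        df = pd.DataFrame(
            {"x_um": xs, "y_um": ys, "neun": True, "cfos": False, "gad": False}
        )
        sq = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        edge = np.array([[0.0, 0.0], [0.0, 1000.0]])
        return SectionPattern("sq", "r", "contra", sq, edge, df)

    def test_equal_area_stripes_on_square(self):
        sec = self._square_section([100, 350, 600, 850], [500, 500, 500, 500])
        part = stripe_partition(sec, marker="neun", thickness=250.0, k=4)
        np.testing.assert_allclose(part.areas, 250_000.0, rtol=1e-6)
        np.testing.assert_array_equal(part.observed, [1, 1, 1, 1])

    def test_counts_conserved_and_last_stripe_absorbs(self, small_section):
        part = stripe_partition(small_section, marker="neun")
        assert part.observed.sum() == small_section.points["neun"].sum()
        assert part.areas.sum() == pytest.approx(
            small_section.region.area, rel=1e-6
        )

    def test_all_points_in_first_band(self):
        sec = self._square_section([10, 20, 30], [100, 500, 900])
        part = stripe_partition(sec, marker="neun", thickness=100.0, k=5)
        assert part.observed[0] == 3 and part.observed[1:].sum() == 0

    def test_g_statistic_formula_case(self):
        part = StripePartition(
            k=2,
            thickness=1.0,
            areas=np.array([1.0, 1.0]),
            observed=np.array([10.0, 0.0]),
            expected=np.array([5.0, 5.0]),
            n_total=10,
        )
        res = gtest_uniform(part)
        assert res.G == pytest.approx(2 * 10 * math.log(2), rel=1e-9)
        assert res.df == 1

    def test_proportional_counts_give_zero(self):
        part = StripePartition(
            k=3,
            thickness=1.0,
            areas=np.array([1.0, 2.0, 1.0]),
            observed=np.array([5.0, 10.0, 5.0]),
            expected=np.array([5.0, 10.0, 5.0]),
            n_total=20,
        )
        res = gtest_uniform(part)
        assert res.G == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_g_matches_literal_formula_on_random_counts(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 8))
            areas = rng.uniform(0.5, 2.0, k)
            obs = rng.poisson(20, k).astype(float)
            if obs.sum() == 0:
                continue
            exp = areas / areas.sum() * obs.sum()
            part = StripePartition(
                k=k, thickness=1.0, areas=areas, observed=obs,
                expected=exp, n_total=int(obs.sum()),
            )
            res = gtest_uniform(part)
            oracle = 2.0 * sum(
                o * math.log(o / e) for o, e in zip(obs, exp) if o > 0
            )
            assert res.G == pytest.approx(oracle, abs=1e-9)
            assert res.p_value == pytest.approx(
                stats.chi2.sf(oracle, k - 1), abs=1e-12
            )

    def test_zero_expected_with_observed_raises(self):
        part = StripePartition(
            k=2, thickness=1.0, areas=np.array([1.0, 0.0]),
            observed=np.array([5.0, 5.0]), expected=np.array([10.0, 0.0]),
            n_total=10,
        )
        with pytest.raises(ValueError):
            gtest_uniform(part)

    def test_stripe_counts_invariant_under_rigid_motion(self, small_section):
        part0 = stripe_partition(small_section, thickness=40.0, k=4)
        moved = affinity.translate(small_section.region, 500.0, 77.0)
        pts = small_section.points.copy()
        pts["x_um"] += 500.0
        pts["y_um"] += 77.0
        sec2 = SectionPattern(
            "m", "r", "contra", moved,
            small_section.lateral_edge + np.array([500.0, 77.0]), pts,
        )
        part1 = stripe_partition(sec2, thickness=40.0, k=4)
        np.testing.assert_array_equal(part0.observed, part1.observed)
        np.testing.assert_allclose(part0.areas, part1.areas, rtol=1e-6)


class TestMedianLateralization:
    def test_lateral_distance_respects_edge(self, small_section):
        d = lateral_distance(
            small_section.coords("neun"), small_section.lateral_edge
        )
        assert np.all(d >= 0)
        assert d.max() <= small_section.lateromedial_extent + 1e-6

    def test_strong_bias_gives_small_p(self):
        sec = make_section(
            SectionParams(**SMALL_GEOMETRY, lateral_bias_scale=25.0), seed=9
        )
        res = median_lateralization_test(sec, N_sim=1000, seed=0)
        assert res.p_value < 0.01

    def test_observed_smaller_than_all_sim_reports_bound(self):
        sec = make_section(
            SectionParams(**SMALL_GEOMETRY, lateral_bias_scale=5.0), seed=2
        )
        res = median_lateralization_test(sec, N_sim=200, seed=1)
        if res.n_below == 0:
            assert res.p_label.startswith("<")


class TestHolm:
    def test_worked_examples(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])
        np.testing.assert_allclose(
            holm_adjust([0.05, 0.05, 0.05]), [0.15, 0.15, 0.15]
        )

    def test_empty_input(self):
        assert holm_adjust([]).size == 0

    def test_matches_statsmodels_on_random_pvalues(self, rng):
        p = rng.uniform(size=15)
        mine = holm_adjust(p)
        _, ref, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])
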