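"""Monte Carlo damage model: predicates, placement, simulation, summaries."""

import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

from shuttlesim.damage import (
    DamageCriterion,
    DamageDistribution,
    PlacementSample,
    SegmentIndex,
    compare_geometries,
    count_damaged,
    fit_gaussian,
    place_contour,
    placement_region,
    run_simulation,
    sample_placement,
)
from shuttlesim.geometry import (
    RectangularSection,
    SectionPolygon,
    make_contour,
)
from shuttlesim.vasculature import (
    Projected2DSegment,
    SynthNetworkConfig,
    generate_synthetic,
    project_to_plane,
)

CENTERLINE = DamageCriterion("centerline")
FULL_WIDTH = DamageCriterion("full-width")
IDENTITY = PlacementSample(0.0, 0.0, 0.0)


def centered_rect_contour(width, height):
    """Axis-aligned rectangle contour whose centroid is the origin."""
    w, h = width / 2.0, height / 2.0
    return SectionPolygon(np.array([[-w, -h], [w, -h], [w, h], [-w, h]]))


def chord_sampling_oracle(poly, seg, mode, n=2001):
    """Independent predicate: dense sampling of transversal chords.

    centerline: does any centreline sample point lie strictly inside?
    full-width: is there a t where the full cross-chord lies inside?
    """
    p0, p1 = np.asarray(seg.q0), np.asarray(seg.q1)
    ts = np.linspace(0.0, 1.0, n)
    if mode == "centerline":
        from shapely.geometry import Point

        return any(poly.contains(Point(p0 + t * (p1 - p0))) for t in ts)
    u = (p1 - p0) / np.linalg.norm(p1 - p0)
    nv = np.array([-u[1], u[0]]) * seg.diameter_um / 2.0
    for t in ts:
        c = p0 + t * (p1 - p0)
        if poly.covers(LineString([c + nv, c - nv])):
            return True
    return False


class TestPlacement:
    def test_point_degenerate_bounds(self, rng):
        s = sample_placement((5.0, 5.0, -2.0, -2.0), rng)
        assert (s.x, s.y) == (5.0, -2.0)

    def test_reversed_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_placement((1.0, 0.0, 0.0, 1.0), rng)

    def test_fixed_seed_reproducible(self):
        r1, r2 = np.random.default_rng(9), np.random.default_rng(9)
        for _ in range(100):
            a = sample_placement((0, 10, 0, 10), r1)
            b = sample_placement((0, 10, 0, 10), r2)
            assert a == b

    def test_uniformity_over_grid(self):
        """10^4 placements pass a chi-square uniformity test on a 10x10 grid."""
        from scipy.stats import chi2

        rng = np.random.default_rng(2024)
        xs, ys, thetas = [], [], []
        for _ in range(10_000):
            s = sample_placement((0, 10, 0, 10), rng)
            xs.append(s.x)
            ys.append(s.y)
            thetas.append(s.theta)
        hist, _, _ = np.histogram2d(xs, ys, bins=[np.linspace(0, 10, 11)] * 2)
        expected = 10_000 / 100
        stat = ((hist - expected) ** 2 / expected).sum()
        assert stat < chi2.ppf(0.99, 99)
        assert 0 <= min(thetas) and max(thetas) < 2 * np.pi

    def test_rotation_about_centroid(self, tbeam_section):
        contour = make_contour(tbeam_section)
        placed = place_contour(contour, PlacementSample(100.0, 50.0, 1.23))
        assert placed.centroid.x == pytest.approx(100.0)
        assert placed.centroid.y == pytest.approx(50.0)
        assert placed.area == pytest.approx(contour.area, rel=1e-9)

    def test_region_shrinks_by_circumradius(self):
        segs = [Projected2DSegment(1, (0, 0), (1000, 1000), 5.0)]
        contour = centered_rect_contour(20, 10)
        xmin, xmax, ymin, ymax = placement_region(segs, contour)
        r = np.hypot(10, 5)
        assert xmin == pytest.approx(r) and xmax == pytest.approx(1000 - r)
        unx = placement_region(segs, unclipped=True)
        assert unx == (0.0, 1000.0, 0.0, 1000.0)


class TestTransectionPredicates:
    def test_empty_segment_list(self):
        contour = centered_rect_contour(20, 10)
        assert count_damaged(contour, IDENTITY, [], CENTERLINE) == 0

    def test_bisected_segment_counts_once_in_both_modes(self):
        # horizontal vessel crossed perpendicularly by a footprint wider than
        # its diameter: a constructed certain transection
        seg = Projected2DSegment(1, (-100.0, 0.0), (100.0, 0.0), 6.0)
        contour = centered_rect_contour(10, 40)
        for crit in (CENTERLINE, FULL_WIDTH):
            assert count_damaged(contour, IDENTITY, [seg], crit) == 1

    def test_tangency_not_damaged(self):
        # vessel centreline touching the footprint edge from outside
        seg = Projected2DSegment(1, (-100.0, 5.0), (100.0, 5.0), 6.0)
        contour = centered_rect_contour(10, 10)  # top edge at y = 5
        assert count_damaged(contour, IDENTITY, [seg], CENTERLINE) == 0

    def test_partial_width_crossing_distinguishes_modes(self):
        # footprint overlaps the band but not the full vessel width
        seg = Projected2DSegment(1, (-100.0, 0.0), (100.0, 0.0), 12.0)
        sliver = SectionPolygon(
            np.array([[-5.0, -1.0], [5.0, -1.0], [5.0, 14.0], [-5.0, 14.0]])
        )
        at_rest = PlacementSample(0.0, 6.5, 0.0)  # centroid stays put
        # sliver spans y in [-1, 14]: crosses the centreline (y=0) but not
        # the full band y in [-6, 6]
        assert count_damaged(sliver, at_rest, [seg], CENTERLINE) == 1
        assert count_damaged(sliver, at_rest, [seg], FULL_WIDTH) == 0

    def test_covered_segment_end_is_transected(self):
        seg = Projected2DSegment(1, (0.0, 0.0), (100.0, 0.0), 6.0)
        block = SectionPolygon(
            np.array([[-20.0, -20.0], [10.0, -20.0], [10.0, 20.0], [-20.0, 20.0]])
        )
        at_rest = PlacementSample(-5.0, 0.0, 0.0)  # centroid stays put
        assert count_damaged(block, at_rest, [seg], FULL_WIDTH) == 1

    def test_degenerate_projection_handling(self):
        pt_seg = Projected2DSegment(1, (0.0, 0.0), (0.0, 0.0), 6.0)
        big = centered_rect_contour(40, 40)
        small = centered_rect_contour(4, 4)  # smaller than the vessel disc
        assert count_damaged(big, IDENTITY, [pt_seg], CENTERLINE) == 1
        assert count_damaged(big, IDENTITY, [pt_seg], FULL_WIDTH) == 1
        assert count_damaged(small, IDENTITY, [pt_seg], FULL_WIDTH) == 0

    def test_toy_network_against_chord_sampling_oracle(self, tbeam_section):
        segs = [
            Projected2DSegment(1, (-30.0, 4.0), (40.0, 6.0), 5.0),
            Projected2DSegment(2, (-10.0, -30.0), (-12.0, 50.0), 8.0),
            Projected2DSegment(3, (50.0, 50.0), (90.0, 90.0), 4.0),
            Projected2DSegment(4, (0.0, 20.0), (5.0, 21.0), 3.0),
            Projected2DSegment(5, (-40.0, 19.0), (60.0, 19.5), 2.0),
        ]
        contour = make_contour(tbeam_section)
        placement = PlacementSample(3.0, 10.0, 0.7)
        poly = place_contour(contour, placement)
        for crit in (CENTERLINE, FULL_WIDTH):
            expected = sum(
                chord_sampling_oracle(poly, s, crit.mode) for s in segs
            )
            assert count_damaged(contour, placement, segs, crit) == expected
            idx = SegmentIndex(segs)
            assert count_damaged(contour, placement, segs, crit, index=idx) == expected


class TestBruteForceVsIndexed:
    def test_random_small_networks_agree(self):
        rng = np.random.default_rng(77)
        contour = centered_rect_contour(30, 12)
        for case in range(30):
            n = rng.integers(1, 40)
            pts = rng.uniform(-150, 150, (n, 4))
            segs = [
                Projected2DSegment(
                    i, tuple(p[:2]), tuple(p[2:]), float(rng.uniform(2, 10))
                )
                for i, p in enumerate(pts)
            ]
            idx = SegmentIndex(segs)
            placement = sample_placement((-100, 100, -100, 100), rng)
            for crit in (CENTERLINE, FULL_WIDTH):
                brute = count_damaged(contour, placement, segs, crit)
                fast = count_damaged(contour, placement, segs, crit, index=idx)
                assert brute == fast


class TestMonotonicity:
    def test_containing_footprint_never_counts_fewer(self):
        """In centerline mode a larger footprint dominates a contained one."""
        rng = np.random.default_rng(31)
        small = centered_rect_contour(20, 8)
        large = centered_rect_contour(40, 30)  # geometrically contains small
        pts = rng.uniform(-200, 200, (300, 4))
        segs = [
            Projected2DSegment(i, tuple(p[:2]), tuple(p[2:]), 5.0)
            for i, p in enumerate(pts)
        ]
        for _ in range(25):
            placement = sample_placement((-150, 150, -150, 150), rng)
            c_small = count_damaged(small, placement, segs, CENTERLINE)
            c_large = count_damaged(large, placement, segs, CENTERLINE)
            assert c_large >= c_small


class TestSimulation:
    def make_segments(self, seed=7):
        net = generate_synthetic(SynthNetworkConfig(seed=seed))
        return project_to_plane(net)

    def test_deterministic_given_seed(self, tbeam_section):
        segs = self.make_segments()
        a = run_simulation(tbeam_section, segs, n_trials=50, seed=123)
        b = run_simulation(tbeam_section, segs, n_trials=50, seed=123)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert a.mean == b.mean and a.deviation == b.deviation

    def test_metadata_recorded(self, tbeam_section):
        segs = self.make_segments()
        d = run_simulation(
            tbeam_section, segs, n_trials=10, seed=5, network_id="synth7"
        )
        assert d.seed == 5
        assert d.network_id == "synth7"
        assert d.criterion.mode == "centerline"
        assert d.counts.size == 10
        assert (d.counts >= 0).all()

    def test_summary_reproducible_from_counts(self, tbeam_section):
        segs = self.make_segments()
        d = run_simulation(tbeam_section, segs, n_trials=80, seed=2)
        assert d.mean == pytest.approx(d.counts.mean())
        assert d.deviation == pytest.approx(d.counts.std(ddof=1))

    def test_empty_network_with_explicit_region_counts_zero(self, tbeam_section):
        d = run_simulation(
            tbeam_section, [], n_trials=10, seed=0, region=(0, 100, 0, 100)
        )
        assert (d.counts == 0).all()

    def test_needs_at_least_one_trial(self, tbeam_section):
        with pytest.raises(ValueError):
            run_simulation(tbeam_section, self.make_segments(), n_trials=0, seed=0)

    def test_mean_matches_integral_geometry(self):
        """Centerline-mode mean equals lambda*(A + l_bar*P/pi) for a convex footprint.

        For isotropic segments with uniform midpoints, integral geometry gives
        the expected number hitting a convex region K as the areal midpoint
        intensity times (area(K) + mean_length * perimeter(K) / pi).  The
        prediction is an ensemble quantity, so the Monte Carlo averages over
        independent network replicates as well as placements; the standard
        error across replicate means covers both randomness sources.
        """
        box = (600.0, 600.0, 300.0)
        rho, median_len, sigma_len = 4e-4, 60.0, 0.6
        rect = RectangularSection(65, 34)
        area, perim = 65.0 * 34.0, 2 * (65.0 + 34.0)
        mean_len_3d = median_len * np.exp(sigma_len**2 / 2)
        lam = rho * box[2] / mean_len_3d  # projected midpoints per µm²
        lbar = mean_len_3d * np.pi / 4.0  # isotropic 3-D sticks: E[sin(polar)]
        expected = lam * (area + lbar * perim / np.pi)
        margin = 150.0  # keep the footprint where the process is stationary
        region = (margin, box[0] - margin, margin, box[1] - margin)
        replicate_means = []
        for seed in range(40):
            cfg = SynthNetworkConfig(
                box_um=box,
                length_density_um_per_um3=rho,
                segment_length_dist=("lognormal", {"median": median_len, "sigma": sigma_len}),
                seed=seed,
            )
            segs = project_to_plane(generate_synthetic(cfg), "z")
            d = run_simulation(
                rect, segs, n_trials=40, seed=1000 + seed,
                criterion=CENTERLINE, region=region,
            )
            replicate_means.append(d.mean)
        replicate_means = np.array(replicate_means)
        se = replicate_means.std(ddof=1) / np.sqrt(replicate_means.size)
        assert abs(replicate_means.mean() - expected) < 3 * se


class TestGaussianFit:
    def test_constant_counts(self):
        assert fit_gaussian([4, 4, 4, 4]) == (4.0, 0.0)

    def test_matches_sample_moments(self, rng):
        x = rng.integers(0, 20, 500)
        m, s = fit_gaussian(x)
        assert m == pytest.approx(x.mean())
        assert s == pytest.approx(x.std(ddof=1))

    def test_recovers_normal_parameters(self):
        rng = np.random.default_rng(555)
        draws = rng.normal(10.0, 2.0, 1000)
        m, s = fit_gaussian(draws)
        se_mean = 2.0 / np.sqrt(1000)
        assert abs(m - 10.0) < 3 * se_mean
        se_sd = 2.0 / np.sqrt(2 * 999)
        assert abs(s - 2.0) < 3 * se_sd

    def test_histogram_variant_close_to_moments(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(12.0, 3.0, 2000).round()
        m_mom, s_mom = fit_gaussian(draws, method="moments")
        m_fit, s_fit = fit_gaussian(draws, method="histogram")
        assert m_fit == pytest.approx(m_mom, abs=0.3)
        assert s_fit == pytest.approx(s_mom, abs=0.3)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian([3])


class TestComparison:
    def fake_dist(self, mean):
        counts = np.array([mean - 1, mean, mean + 1], dtype=float)
        return DamageDistribution(
            counts, float(mean), 1.0, "g", "n", 0, CENTERLINE
        )

    def test_study_means_reduction(self):
        c = compare_geometries(self.fake_dist(6.23), self.fake_dist(9.84))
        assert c.reduction_percent == pytest.approx(36.7, abs=0.1)

    def test_identical_distributions(self):
        c = compare_geometries(self.fake_dist(5.0), self.fake_dist(5.0))
        assert c.reduction_percent == pytest.approx(0.0)
        assert c.fold_change == pytest.approx(1.0)

    def test_fold_change(self):
        c = compare_geometries(self.fake_dist(1.4), self.fake_dist(13.6))
        assert c.fold_change == pytest.approx(9.7, abs=0.02)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            compare_geometries(self.fake_dist(1.0), self.fake_dist(0.0))

    def test_criterion_validation(self):
        with pytest.raises(ValueError):
            DamageCriterion("sideways")
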