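import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from songspace.geometry import (balanced_subsample_dimorphism,
                                dimorphism_metrics, element_diversity_scores,
                                mcp)


def brute_force_mcp_area(points, retain):
    """Independent oracle: nearest-to-centroid retention, monotone-chain
    hull, shoelace area. Shares no geometry code with the implementation."""
    pts = np.asarray(points, float)
    n = len(pts)
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1)
    kept = pts[np.argsort(d, kind="stable")[: math.ceil(retain * n)]]
    kept = np.unique(kept, axis=0)
    if len(kept) < 3:
        return 0.0
    P = sorted(map(tuple, kept))

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in P:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(P):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        return 0.0
    area = 0.0
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


class TestMCP:
    def test_unit_square_full_retention(self):
        poly = mcp(np.array([[0, 0], [0, 1], [1, 0], [1, 1.0]]), 1.0)
        assert poly.area == pytest.approx(1.0)
        assert poly.n_points_used == 4 and not poly.degenerate

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        poly = mcp(pts, 0.95)
        assert poly.area == 0.0 and poly.degenerate

    def test_outlier_dropped_at_95(self, rng):
        theta = np.linspace(0, 2 * np.pi, 19, endpoint=False)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        pts = np.vstack([circle, [[100.0, 0.0]]])
        poly = mcp(pts, 0.95)
        assert poly.n_points_used == 19
        assert poly.area == pytest.approx(
            brute_force_mcp_area(circle, 1.0), abs=1e-9)

    def test_retained_count_ceil_convention(self, rng):
        pts = rng.normal(size=(17, 2))
        poly = mcp(pts, 0.9)
        assert poly.n_points_used == math.ceil(0.9 * 17)

    def test_shoelace_consistency(self, rng):
        pts = rng.normal(size=(40, 2))
        poly = mcp(pts, 0.95)
        v = poly.vertices
        shoelace = 0.5 * abs(np.sum(v[:, 0] * np.roll(v[:, 1], -1)
                                    - np.roll(v[:, 0], -1) * v[:, 1]))
        assert poly.area == pytest.approx(shoelace, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mcp(np.empty((0, 2)))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(n=st.integers(3, 120), seed=st.integers(0, 10_000),
           retain=st.sampled_from([0.9, 0.95, 1.0]))
    def test_matches_brute_force_oracle(self, n, seed, retain):
        pts = np.random.default_rng(seed).normal(size=(n, 2))
        assert mcp(pts, retain).area == pytest.approx(
            brute_force_mcp_area(pts, retain), abs=1e-9)


class TestElementDiversity:
    def test_coincident_elements_zero(self):
        coords = np.zeros((5, 2))
        scores = element_diversity_scores(coords, np.repeat("s1", 5))
        assert scores["s1"] == 0.0

    def test_area_scales_quadratically(self):
        sq = np.array([[0, 0], [0, 1], [1, 0], [1, 1.0]])
        coords = np.vstack([sq, sq / 2])
        ids = np.repeat(["big", "small"], 4)
        scores = element_diversity_scores(coords, ids, retain=1.0)
        assert scores["big"] / scores["small"] == pytest.approx(4.0)

    def test_matches_oracle_on_random_songs(self, rng):
        coords = rng.normal(size=(60, 2))
        ids = np.repeat([f"s{i}" for i in range(3)], 20)
        scores = element_diversity_scores(coords, ids)
        for i in range(3):
            assert scores[f"s{i}"] == pytest.approx(
                brute_force_mcp_area(coords[ids == f"s{i}"], 0.95), abs=1e-9)


class TestDimorphismMetrics:
    def test_identical_sets(self, rng):
        pts = rng.normal(size=(30, 2))
        assert dimorphism_metrics(pts, pts) == (1.0, 0.0, 0.0)

    def test_offset_rectangles_analytic(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        overlap, dist, sizediff = dimorphism_metrics(sq, sq + [0.5, 0],
                                                     retain=1.0)
        assert overlap == pytest.approx(1 / 3)
        assert sizediff == pytest.approx(0.0)
        assert dist > 0

    def test_disjoint_sets_zero_overlap(self, rng):
        a = rng.normal(size=(20, 2))
        b = a + 100
        overlap, dist, _ = dimorphism_metrics(a, b)
        assert overlap == 0.0 and dist > 0

    def test_sex_label_exchange_symmetry(self, rng):
        a, b = rng.normal(size=(15, 2)), rng.normal(size=(18, 2)) + 0.5
        m1 = dimorphism_metrics(a, b)
        m2 = dimorphism_metrics(b, a)
        assert m1 == pytest.approx(m2)

    def test_translation_and_scaling_invariance(self, rng):
        a, b = rng.normal(size=(20, 2)), rng.normal(size=(20, 2)) + 1
        base = dimorphism_metrics(a, b)
        shift = np.array([5.0, -3.0])
        shifted = dimorphism_metrics(a + shift, b + shift)
        assert base == pytest.approx(shifted)
        scale = np.array([2.0, 0.5])
        scaled = dimorphism_metrics(a * scale, b * scale)
        # overlap and (z-scored) centroid distance unchanged by axis scaling
        assert base[1] == pytest.approx(scaled[1])

    def test_shift_monotone_in_overlap_and_distance(self, rng):
        from scipy.stats import spearmanr
        shifts = [0.0, 0.5, 1.0, 2.0, 4.0]
        overlaps, dists = [], []
        for s in shifts:
            a = rng.normal(size=(200, 2))
            b = rng.normal(size=(200, 2)) + [s, 0]
            o, d, _ = dimorphism_metrics(a, b)
            overlaps.append(o)
            dists.append(d)
        assert spearmanr(shifts, overlaps).statistic < -0.9
        assert spearmanr(shifts, dists).statistic > 0.9

    def test_degenerate_cases(self):
        line = np.column_stack([np.linspace(0, 1, 5), np.zeros(5)])
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        assert dimorphism_metrics(line, line) == (0.0, 0.0, 0.0)
        o, _, sd = dimorphism_metrics(line, square, retain=1.0)
        assert o == 0.0 and sd == 1.0


class TestBalancedSubsample:
    def test_equal_sizes_zero_variance(self, rng):
        a, b = rng.normal(size=(25, 2)), rng.normal(size=(25, 2))
        res = balanced_subsample_dimorphism(a, b, n_iter=100, seed=1)
        # every iteration uses the full data: rows bit-identical, variance 0
        assert np.all(np.ptp(res.per_iteration, axis=0) == 0.0)
        assert (res.overlap_prop, res.centroid_distance,
                res.area_size_difference) == pytest.approx(
                    dimorphism_metrics(a, b, np.vstack([a, b])))

    def test_deterministic_given_seed(self, rng):
        a, b = rng.normal(size=(50, 2)), rng.normal(size=(12, 2))
        r1 = balanced_subsample_dimorphism(a, b, n_iter=30, seed=9)
        r2 = balanced_subsample_dimorphism(a, b, n_iter=30, seed=9)
        assert np.array_equal(r1.per_iteration, r2.per_iteration)

    def test_resampling_converges(self, rng):
        a = rng.normal(size=(200, 2))
        b = rng.normal(size=(20, 2)) + 0.3
        r100 = balanced_subsample_dimorphism(a, b, n_iter=100, seed=2)
        r1000 = balanced_subsample_dimorphism(a, b, n_iter=1000, seed=3)
        se = r1000.per_iteration[:, 0].std() / np.sqrt(100)
        assert abs(r100.overlap_prop - r1000.overlap_prop) < 3 * se + 1e-12

    def test_invalid_iterations_rejected(self, rng):
        with pytest.raises(ValueError):
            balanced_subsample_dimorphism(rng.normal(size=(5, 2)),
                                          rng.normal(size=(5, 2)), n_iter=0)
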