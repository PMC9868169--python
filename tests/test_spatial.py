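"""Centroid migration, spatial weights, Moran's I and Gi* hot spots."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdikit.errors import DegenerateInputError
from hdikit.grid import GridSpec, ValueGrid
from hdikit.spatial import (
    build_weights,
    centroid_track,
    getis_ord_gistar,
    moran_permutation,
    moran_z,
    morans_i,
    weighted_centroid,
)


def brute_force_moran(values, w_dense):
    """Direct double-sum evaluation of the autocorrelation formula."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    z = x - x.mean()
    s2 = (z**2).sum() / n
    num = sum(w_dense[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return num / (s2 * w_dense.sum())


class TestCentroid:
    def test_uniform_field_centers_on_grid(self):
        spec = GridSpec(4, 4, 1000.0, 0.0, 4000.0)
        x, y = weighted_centroid(ValueGrid(spec, np.ones((4, 4))))
        assert (x, y) == (2000.0, 2000.0)

    def test_single_positive_cell(self):
        spec = GridSpec(3, 3, 1000.0, 0.0, 3000.0)
        vals = np.zeros((3, 3))
        vals[2, 0] = 5.0
        x, y = weighted_centroid(ValueGrid(spec, vals))
        assert (x, y) == (500.0, 500.0)

    def test_two_by_two_weighted_mean(self):
        spec = GridSpec(2, 2, 1000.0, 0.0, 2000.0)
        vals = np.array([[1.0, 3.0], [1.0, 3.0]])
        x, y = weighted_centroid(ValueGrid(spec, vals))
        # columns at x = 500 and 1500 weighted 2:6
        assert x == pytest.approx((500 * 2 + 1500 * 6) / 8)
        assert y == pytest.approx(1000.0)

    def test_all_zero_raises(self):
        spec = GridSpec(2, 2, 1000.0, 0.0, 2000.0)
        with pytest.raises(DegenerateInputError):
            weighted_centroid(ValueGrid(spec, np.zeros((2, 2))))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(0.1, 100.0), shift=st.floats(-1e5, 1e5))
    def test_scale_invariant_and_translation_equivariant(self, scale, shift):
        rng = np.random.default_rng(7)
        vals = rng.random((5, 5)) + 0.1
        spec = GridSpec(5, 5, 1000.0, 0.0, 5000.0)
        x0, y0 = weighted_centroid(ValueGrid(spec, vals))
        xs, ys = weighted_centroid(ValueGrid(spec, vals * scale))
        assert (xs, ys) == pytest.approx((x0, y0), rel=1e-9)
        spec2 = GridSpec(5, 5, 1000.0, shift, 5000.0 + shift, "local-meters")
        xt, yt = weighted_centroid(ValueGrid(spec2, vals))
        assert xt - x0 == pytest.approx(shift, abs=1e-6)
        assert yt - y0 == pytest.approx(shift, abs=1e-6)


class TestCentroidTrack:
    def test_printed_segment_speed(self):
        """A 602.80 m shift over a 5-year interval moves at 120.56 m/yr."""
        pts = [("2010", 0.0, 0.0), ("2015", 0.0, -602.80)]
        track = centroid_track(pts, [5.0])
        seg = track.segments[0]
        assert seg["displacement_m"] == pytest.approx(602.80)
        assert seg["speed_m_per_year"] == pytest.approx(120.56)

    def test_stationary_centroid(self):
        track = centroid_track([("a", 10.0, 10.0), ("b", 10.0, 10.0)], [5.0])
        assert track.segments[0]["displacement_m"] == 0.0
        assert track.segments[0]["speed_m_per_year"] == 0.0

    def test_three_four_five_triangle(self):
        track = centroid_track([("a", 0.0, 0.0), ("b", 300.0, 400.0)], [2.0])
        seg = track.segments[0]
        assert seg["displacement_m"] == pytest.approx(500.0)
        assert seg["bearing_deg"] == pytest.approx(math.degrees(math.atan2(300, 400)))
        assert seg["direction"] == "NE"
        assert seg["speed_m_per_year"] == pytest.approx(250.0)

    def test_southwest_direction(self):
        track = centroid_track([("a", 0.0, 0.0), ("b", -100.0, -100.0)], [1.0])
        assert track.segments[0]["direction"] == "SW"

    def test_non_positive_interval_raises(self):
        with pytest.raises(ValueError):
            centroid_track([("a", 0.0, 0.0), ("b", 1.0, 1.0)], [0.0])


class TestWeights:
    def test_two_by_two_rook_counts(self):
        spec = GridSpec(2, 2, 1000.0, 0.0, 2000.0)
        w = build_weights(spec, None, "rook")
        counts = np.asarray(w.w.sum(axis=1)).ravel()
        assert counts.tolist() == [2, 2, 2, 2]

    def test_three_by_three_queen_center(self):
        spec = GridSpec(3, 3, 1000.0, 0.0, 3000.0)
        w = build_weights(spec, None, "queen")
        counts = np.asarray(w.w.sum(axis=1)).ravel()
        assert counts[4] == 8  # center cell

    @pytest.mark.parametrize("scheme", ["rook", "queen"])
    def test_random_mask_matches_pairwise_scan(self, scheme, rng):
        spec = GridSpec(6, 6, 1000.0, 0.0, 6000.0)
        mask = rng.random((6, 6)) > 0.3
        mask.flat[:2] = True  # keep >= 2 cells
        w = build_weights(spec, mask, scheme)
        cells = w.cells
        dense = np.zeros((w.n, w.n))
        for a in range(w.n):
            for b in range(w.n):
                if a == b:
                    continue
                di = abs(cells[a, 0] - cells[b, 0])
                dj = abs(cells[a, 1] - cells[b, 1])
                if scheme == "rook":
                    dense[a, b] = 1.0 if di + dj == 1 else 0.0
                else:
                    dense[a, b] = 1.0 if max(di, dj) == 1 else 0.0
        np.testing.assert_array_equal(w.w.toarray(), dense)

    def test_distance_band_symmetric_no_self(self):
        spec = GridSpec(4, 4, 1000.0, 0.0, 4000.0)
        w = build_weights(spec, None, "distance_band", d=2000.0)
        dense = w.w.toarray()
        np.testing.assert_array_equal(dense, dense.T)
        assert (np.diag(dense) == 0).all()

    def test_band_below_cell_size_raises(self):
        spec = GridSpec(3, 3, 1000.0, 0.0, 3000.0)
        with pytest.raises(DegenerateInputError):
            build_weights(spec, None, "distance_band", d=500.0)


class TestMoran:
    def test_checkerboard_rook_is_minus_one(self):
        spec = GridSpec(8, 8, 1000.0, 0.0, 8000.0)
        board = (np.indices((8, 8)).sum(0) % 2).astype(float)
        w = build_weights(spec, None, "rook")
        assert morans_i(board.ravel(), w) == pytest.approx(-1.0, abs=1e-12)

    def test_block_pattern_positive(self):
        spec = GridSpec(6, 6, 1000.0, 0.0, 6000.0)
        vals = np.zeros((6, 6))
        vals[:, 3:] = 5.0
        w = build_weights(spec, None, "rook")
        assert morans_i(vals.ravel(), w) > 0

    def test_matches_brute_force_double_sum(self, rng):
        spec = GridSpec(5, 5, 1000.0, 0.0, 5000.0)
        vals = rng.random(25)
        for scheme in ("rook", "queen"):
            w = build_weights(spec, None, scheme)
            assert morans_i(vals, w) == pytest.approx(
                brute_force_moran(vals, w.w.toarray()), abs=1e-12
            )

    def test_blocks_trend_toward_positive_with_size(self):
        last = -1.0 - 1e-12  # block=1 is the checkerboard, exactly -1
        for block in (1, 2, 4):
            size = 8
            spec = GridSpec(size, size, 1000.0, 0.0, size * 1000.0)
            vals = ((np.indices((size, size)) // block).sum(0) % 2).astype(float)
            w = build_weights(spec, None, "rook")
            i = morans_i(vals.ravel(), w)
            assert i > last
            last = i

    def test_zero_variance_raises(self):
        spec = GridSpec(3, 3, 1000.0, 0.0, 3000.0)
        w = build_weights(spec, None, "rook")
        with pytest.raises(DegenerateInputError):
            morans_i(np.ones(9), w)

    def test_gradient_field_is_significant(self):
        spec = GridSpec(10, 10, 1000.0, 0.0, 10_000.0)
        grad = np.add.outer(np.arange(10.0), np.arange(10.0))
        w = build_weights(spec, None, "queen")
        _, z, p = moran_z(grad.ravel(), w)
        assert z > 2.576 and p < 0.01

    def test_permutation_mean_matches_expectation(self, rng):
        spec = GridSpec(6, 6, 1000.0, 0.0, 6000.0)
        vals = rng.random(36)
        w = build_weights(spec, None, "queen")
        res = moran_permutation(vals, w, n_permutations=2000, seed=42)
        e_i = -1.0 / 35
        se = res["sd"] / math.sqrt(2000)
        assert abs(res["mean"] - e_i) < 3 * se


class TestGiStar:
    def test_full_band_gives_unit_gi(self, rng):
        spec = GridSpec(5, 5, 1000.0, 0.0, 5000.0)
        vg = ValueGrid(spec, rng.random((5, 5)) + 0.1)
        res = getis_ord_gistar(vg, d=1e9)
        np.testing.assert_allclose(res.gi_star, 1.0, atol=1e-12)

    def test_numerator_identity(self, rng):
        spec = GridSpec(6, 6, 1000.0, 0.0, 6000.0)
        vals = rng.random((6, 6)) + 0.1
        vg = ValueGrid(spec, vals)
        res = getis_ord_gistar(vg, d=2000.0)
        w = build_weights(spec, None, "distance_band", d=2000.0)
        dense = w.w.toarray() + np.eye(36)
        lhs = np.nansum(res.gi_star) * vals.sum()
        rhs = (dense @ vals.ravel()).sum()
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_planted_cluster_flagged_hot(self):
        rng = np.random.default_rng(99)
        spec = GridSpec(30, 30, 1000.0, 0.0, 30_000.0)
        vals = rng.random((30, 30))
        rr, cc = np.mgrid[0:30, 0:30]
        cluster = (rr - 15) ** 2 + (cc - 15) ** 2 <= 16
        vals[cluster] += 3 * vals.std()
        res = getis_ord_gistar(ValueGrid(spec, vals))
        flagged = np.isin(res.category[cluster], ["hot95", "hot99"])
        assert flagged.mean() >= 0.9

    def test_z_mean_near_zero_on_random_field(self):
        rng = np.random.default_rng(2024)
        spec = GridSpec(50, 50, 1000.0, 0.0, 50_000.0)
        vals = rng.random((50, 50))
        res = getis_ord_gistar(ValueGrid(spec, vals))
        assert abs(np.nanmean(res.z_scores)) < 0.1

    def test_constant_field_not_significant(self):
        spec = GridSpec(4, 4, 1000.0, 0.0, 4000.0)
        res = getis_ord_gistar(ValueGrid(spec, np.full((4, 4), 2.0)))
        assert (res.z_scores == 0).all()
        assert (res.category == "not_significant").all()

    def test_zero_sum_field_raises(self):
        spec = GridSpec(3, 3, 1000.0, 0.0, 3000.0)
        with pytest.raises(DegenerateInputError):
            getis_ord_gistar(ValueGrid(spec, np.zeros((3, 3))))
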