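import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adhescan.segmentation import (
    compute_iws,
    extract_tracks,
    find_cell_centers,
    interpolate_frame,
    interpolated_pitch,
    segment_frame,
    voronoi_partition,
)


def brute_force_nearest(generators, shape):
    """Independent O(pixels × generators) Voronoi oracle (tie → lowest index)."""
    gen = np.asarray(generators)
    labels = np.empty(shape, dtype=int)
    for r in range(shape[0]):
        for c in range(shape[1]):
            d2 = (gen[:, 0] - r) ** 2 + (gen[:, 1] - c) ** 2
            labels[r, c] = int(np.argmin(d2))
    return labels


def brute_force_maxima(frame, min_prominence):
    """All strict 8-neighbour local maxima above the median + prominence."""
    out = []
    med = np.median(frame)
    h, w = frame.shape
    for r in range(h):
        for c in range(w):
            v = frame[r, c]
            if v - med < min_prominence:
                continue
            neigh = [
                frame[rr, cc]
                for rr in range(max(r - 1, 0), min(r + 2, h))
                for cc in range(max(c - 1, 0), min(c + 2, w))
                if (rr, cc) != (r, c)
            ]
            if all(v > n for n in neigh):
                out.append((r, c))
    return set(out)


class TestInterpolation:
    def test_identity_at_k0(self):
        frame = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(interpolate_frame(frame, 0), frame)

    def test_bilinear_center_value(self):
        fine = interpolate_frame(np.array([[0.0, 0.0], [0.0, 4.0]]), 1)
        assert fine.shape == (3, 3)
        assert fine[1, 1] == pytest.approx(1.0)  # mean of the four corners

    @settings(deadline=None, max_examples=25)
    @given(
        st.integers(0, 4),
        st.integers(2, 6),
        st.integers(2, 6),
        st.integers(0, 2**31 - 1),
    )
    def test_knots_preserved(self, k, h, w, seed):
        """Any refinement reproduces the original values at the original nodes."""
        frame = np.random.default_rng(seed).normal(size=(h, w))
        fine = interpolate_frame(frame, k)
        f = 2**k
        np.testing.assert_allclose(fine[::f, ::f], frame, atol=1e-12)

    def test_pitch_halves_per_degree(self):
        assert interpolated_pitch(25.0, 4) == pytest.approx(1.5625)

    def test_invalid_degree(self):
        with pytest.raises(ValueError):
            interpolate_frame(np.zeros((2, 2)), -1)
        with pytest.raises(ValueError):
            interpolate_frame(np.zeros((2, 2)), 1.5)

    def test_iws_converges_with_interpolation_degree(self, single_cell_run):
        """Once the interpolated pixel is fine enough, one more refinement
        changes the measured IWS by less than 2%."""
        cfg, stack, truth, _ = single_cell_run
        iws = {}
        for k in (4, 5):
            segs = segment_frame(stack.frame(-1), cfg.at_model, cfg.pixel_pitch, k=k)
            iws[k] = segs[0].iws
        assert abs(iws[5] - iws[4]) / iws[4] < 0.02


class TestFindCellCenters:
    def test_constant_frame_empty(self):
        assert find_cell_centers(np.full((20, 20), 7.0), 1.0, 3.0) == []

    def test_single_bump_single_center(self):
        yy, xx = np.mgrid[0:21, 0:21]
        frame = 100.0 * np.exp(-((yy - 10.0) ** 2 + (xx - 7.0) ** 2) / 18.0)
        centers = find_cell_centers(frame, 10.0, 3.0)
        assert centers == [(10, 7)]

    def test_two_bumps_match_brute_force(self):
        yy, xx = np.mgrid[0:30, 0:30]
        frame = 100.0 * np.exp(-((yy - 10.0) ** 2 + (xx - 10.0) ** 2) / 8.0)
        frame += 80.0 * np.exp(-((yy - 10.0) ** 2 + (xx - 20.0) ** 2) / 8.0)
        centers = find_cell_centers(frame, 10.0, 3.0)
        assert set(centers) == brute_force_maxima(frame, 10.0)
        assert centers[0] == (10, 10)  # higher peak first

    def test_separation_pruning_keeps_higher(self):
        frame = np.zeros((10, 10))
        frame[4, 4] = 50.0
        frame[4, 6] = 40.0
        assert find_cell_centers(frame, 1.0, 3.0) == [(4, 4)]
        assert set(find_cell_centers(frame, 1.0, 2.0)) == {(4, 4), (4, 6)}


class TestVoronoi:
    def test_single_generator_owns_everything(self):
        labels = voronoi_partition([(3, 3)], (8, 8))
        assert np.all(labels == 0)

    def test_perpendicular_bisector_with_tie_rule(self):
        labels = voronoi_partition([(0, 0), (0, 10)], (1, 11))
        np.testing.assert_array_equal(labels[0, :5], 0)
        np.testing.assert_array_equal(labels[0, 6:], 1)
        assert labels[0, 5] == 0  # equidistant -> lowest generator index

    @settings(deadline=None, max_examples=10)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        gens = [tuple(p) for p in rng.integers(0, 40, (n, 2))]
        gens = list(dict.fromkeys(gens))  # distinct generators
        labels = voronoi_partition(gens, (40, 40))
        np.testing.assert_array_equal(labels, brute_force_nearest(gens, (40, 40)))

    def test_zero_generators_error(self):
        with pytest.raises(ValueError, match="empty segmentation"):
            voronoi_partition([], (5, 5))


class TestComputeIws:
    def test_empty_pixel_set(self):
        assert compute_iws(np.array([]), 625.0) == 0.0

    def test_hand_computed_value(self):
        # 625 µm² × (1200 + 800 + 500) pm = 1,562,500 pm·µm²
        assert compute_iws(np.array([1200.0, 800.0, 500.0]), 625.0) == 1_562_500.0

    def test_linearity(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1000, 50)
        assert compute_iws(2 * vals, 10.0) == pytest.approx(2 * compute_iws(vals, 10.0))

    def test_iws_monotone_in_threshold(self, single_cell_run):
        """Raising the threshold can only remove pixels: IWS non-increasing."""
        _, stack, _, _ = single_cell_run
        fine = interpolate_frame(stack.frame(-1), 2)
        pixel_area = interpolated_pitch(25.0, 2) ** 2
        thresholds = np.linspace(0, fine.max(), 25)
        iws = [compute_iws(fine[fine > th], pixel_area) for th in thresholds]
        assert np.all(np.diff(iws) <= 0)


class TestSegmentFrame:
    def test_empty_frame(self, reference_at_model):
        assert segment_frame(np.zeros((40, 40)), reference_at_model, 25.0) == []

    def test_single_cell_area_close_to_truth(self, single_cell_run):
        cfg, stack, truth, _ = single_cell_run
        segs = segment_frame(stack.frame(-1), cfg.at_model, cfg.pixel_pitch, k=4)
        assert len(segs) == 1
        assert segs[0].area == pytest.approx(truth.area[-1, 0], rel=0.05)
        assert segs[0].iws == pytest.approx(truth.iws[-1, 0], rel=0.05)
        assert segs[0].ws_max == pytest.approx(truth.peak[-1, 0], rel=1e-6)

    def test_segment_invariants(self, small_population_run):
        cfg, stack, _, _ = small_population_run
        segs = segment_frame(stack.frame(-1), cfg.at_model, cfg.pixel_pitch, k=2)
        assert segs
        for seg in segs:
            assert np.isin(np.ravel_multi_index(seg.generator, (317, 317)), seg.segment_pixels)
            assert np.all(np.isin(seg.above_pixels, seg.segment_pixels))
            assert 0.0 <= seg.iws <= seg.area * seg.ws_max + 1e-9

    def test_two_disjoint_cells_decompose(self, reference_at_model):
        """Summed per-segment IWS equals a manual two-half-plane computation."""
        yy, xx = np.mgrid[0:21, 0:41].astype(float)
        frame = 2000.0 * np.exp(-((yy - 10) ** 2 + (xx - 10) ** 2) / 20.0)
        frame += 1500.0 * np.exp(-((yy - 10) ** 2 + (xx - 30) ** 2) / 20.0)
        segs = segment_frame(frame, reference_at_model, 25.0, k=1, min_separation=100.0)
        assert len(segs) == 2
        fine = interpolate_frame(frame, 1)
        pixel_area = interpolated_pitch(25.0, 1) ** 2
        total = 0.0
        for half in (fine[:, :40], fine[:, 41:]):  # split at the bisector column
            th = reference_at_model.predict(half.max())
            total += compute_iws(half[half > th], pixel_area)
        assert sum(s.iws for s in segs) == pytest.approx(total, rel=1e-6)


class TestExtractTracks:
    def test_zero_cell_stack(self, reference_at_model):
        from adhescan.io import WSStack

        stack = WSStack(np.zeros((3, 20, 20)), 25.0, 3.0)
        assert extract_tracks(stack, reference_at_model) == []

    def test_noiseless_iws_non_decreasing(self, single_cell_run):
        cfg, stack, _, _ = single_cell_run
        (track,) = extract_tracks(stack, cfg.at_model, k=4)
        assert np.all(np.diff(track.iws) >= -1e-9)

    def test_truth_reproduced_after_half_rise(self, single_cell_run):
        """From the spreading half-time onward the pipeline reproduces the
        closed-form IWS/area truth within 5%."""
        cfg, stack, truth, _ = single_cell_run
        (track,) = extract_tracks(stack, cfg.at_model, k=4)
        sel = truth.peak[:, 0] >= 0.5 * truth.peak[-1, 0]
        np.testing.assert_allclose(track.iws[sel], truth.iws[sel, 0], rtol=0.05)
        np.testing.assert_allclose(track.area[sel], truth.area[sel, 0], rtol=0.05)

    def test_population_track_count_and_positions(self, small_population_run):
        cfg, stack, truth, _ = small_population_run
        tracks = extract_tracks(stack, cfg.at_model, k=2)
        assert abs(len(tracks) - cfg.n_cells) <= max(1, int(0.02 * cfg.n_cells))
        # each truth centre has a track generator within one raw pixel
        centers = np.array([t.center_um for t in tracks])
        for _, row in truth.cells.iterrows():
            d = np.hypot(centers[:, 0] - row.y_um, centers[:, 1] - row.x_um)
            assert d.min() <= cfg.pixel_pitch
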