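"""Lucas-Kanade flow estimation and sequence tracking.

Oracles: nested-loop finite differences for gradients, the closed-form
2x2 inverse for the normal-equation solve, analytic shifts of smooth and
speckle images for flow recovery, and forward/backward consistency for
the sequence tracker.
"""

from __future__ import annotations

import numpy as np
import pytest

from diaflow import (
    FrameSequence,
    InputError,
    PhantomSpec,
    SeedPoints,
    assign_groups,
    group_centroids,
    image_gradients,
    lk_point_flow,
    render_sequence,
    track_sequence,
)
from conftest import make_speckle_frame, translate_frame


def gradient_oracle(frame):
    """Double-loop central differences, one-sided at borders."""
    H, W = frame.shape
    gx = np.zeros((H, W))
    gy = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            if 0 < c < W - 1:
                gx[r, c] = (frame[r, c + 1] - frame[r, c - 1]) / 2.0
            elif c == 0:
                gx[r, c] = frame[r, 1] - frame[r, 0]
            else:
                gx[r, c] = frame[r, W - 1] - frame[r, W - 2]
            if 0 < r < H - 1:
                gy[r, c] = (frame[r + 1, c] - frame[r - 1, c]) / 2.0
            elif r == 0:
                gy[r, c] = frame[1, c] - frame[0, c]
            else:
                gy[r, c] = frame[H - 1, c] - frame[H - 2, c]
    return gx, gy


class TestGradients:
    def test_linear_ramp_has_exact_derivatives(self):
        cols = np.arange(12, dtype=float)
        frame = np.tile(3.0 * cols, (10, 1))
        Ix, Iy, It = image_gradients(frame, frame)
        np.testing.assert_allclose(Ix[:, 1:-1], 3.0)
        np.testing.assert_allclose(Iy, 0.0)
        np.testing.assert_allclose(It, 0.0)

    def test_temporal_difference(self, rng):
        frame = rng.random((8, 8)) * 100
        _, _, It = image_gradients(frame, frame + 5.0)
        np.testing.assert_allclose(It, 5.0)

    def test_matches_double_loop_oracle(self, rng):
        f0 = rng.random((14, 17)) * 255
        f1 = rng.random((14, 17)) * 255
        Ix, Iy, It = image_gradients(f0, f1)
        gx, gy = gradient_oracle(f0)
        np.testing.assert_allclose(Ix, gx, atol=1e-10)
        np.testing.assert_allclose(Iy, gy, atol=1e-10)
        np.testing.assert_allclose(It, f1 - f0, atol=1e-10)

    def test_dimension_mismatch_is_error(self):
        with pytest.raises(InputError):
            image_gradients(np.zeros((4, 4)), np.zeros((5, 4)))


class TestPointFlow:
    def test_zero_temporal_difference_gives_zero_flow(self, rng):
        frame = make_speckle_frame(rng)
        Ix, Iy, It = image_gradients(frame, frame)
        fv = lk_point_flow(Ix, Iy, It, (32, 48), m=9)
        assert fv.valid
        assert fv.u == pytest.approx(0.0) and fv.v == pytest.approx(0.0)

    def test_uniform_window_is_invalid(self):
        flat = np.full((32, 32), 100.0)
        Ix, Iy, It = image_gradients(flat, flat + 3.0)
        assert not lk_point_flow(Ix, Iy, It, (16, 16), m=9).valid

    def test_solution_equals_closed_form_inverse(self, rng):
        """Normal-equation solve equals the algebraic 2x2 inverse applied
        to the summed window terms, on 100 random windows."""
        for _ in range(100):
            f0 = rng.random((21, 21)) * 255
            f1 = rng.random((21, 21)) * 255
            Ix, Iy, It = image_gradients(f0, f1)
            m = 2 * int(rng.integers(1, 5)) + 1
            r = m // 2
            row = int(rng.integers(r, 21 - r))
            col = int(rng.integers(r, 21 - r))
            fv = lk_point_flow(Ix, Iy, It, (row, col), m=m, min_eig_floor=1e-12)
            wx = Ix[row - r : row + r + 1, col - r : col + r + 1].ravel()
            wy = Iy[row - r : row + r + 1, col - r : col + r + 1].ravel()
            wt = It[row - r : row + r + 1, col - r : col + r + 1].ravel()
            A = np.array([[wx @ wx, wx @ wy], [wx @ wy, wy @ wy]])
            b = np.array([-(wx @ wt), -(wy @ wt)])
            if fv.valid:
                uv = np.linalg.inv(A) @ b
                assert fv.u == pytest.approx(uv[0], abs=1e-8)
                assert fv.v == pytest.approx(uv[1], abs=1e-8)

    def test_subpixel_shift_of_gaussian_blob(self):
        """A 0.5 px horizontal shift of a smooth blob is recovered within
        0.15 px at the blob flank."""
        rr, cc = np.meshgrid(np.arange(64, dtype=float), np.arange(64, dtype=float), indexing="ij")
        blob = lambda dc: 200.0 * np.exp(-(((rr - 32) ** 2) + (cc - 32 - dc) ** 2) / (2 * 6.0**2))  # noqa: E731
        f0, f1 = blob(0.0), blob(0.5)
        Ix, Iy, It = image_gradients(f0, f1)
        fv = lk_point_flow(Ix, Iy, It, (32, 38), m=9)  # flank, strong gradient
        assert fv.valid
        assert fv.u == pytest.approx(0.5, abs=0.15)
        assert abs(fv.v) <= 0.1

    def test_even_window_rejected(self):
        Ix = Iy = It = np.zeros((10, 10))
        with pytest.raises(InputError):
            lk_point_flow(Ix, Iy, It, (5, 5), m=4)


def _track_pair(f0, f1, points, **kw):
    """Track points across a single frame pair."""
    seq = FrameSequence(
        frames=np.stack([np.clip(f0, 0, 255), np.clip(f1, 0, 255)]).astype(np.uint8),
        frame_interval=0.04,
    )
    seeds = SeedPoints(coords=np.asarray(points, dtype=float), n_requested=len(points), seed=0)
    tracked = track_sequence(seq, seeds, **kw)
    return tracked.trajectories[1] - tracked.trajectories[0], tracked.valid_mask[1]


class TestTrackSequence:
    def test_static_sequence_gives_constant_trajectories(self, rng):
        frame = make_speckle_frame(rng).astype(np.uint8)
        seq = FrameSequence(frames=np.stack([frame] * 6), frame_interval=0.04)
        pts = np.array([[20, 30], [40, 60], [30, 50]], dtype=float)
        seeds = SeedPoints(coords=pts, n_requested=3, seed=0)
        tracked = track_sequence(seq, seeds, m=11)
        assert tracked.valid_mask.all()
        for t in range(6):
            np.testing.assert_allclose(tracked.trajectories[t], pts, atol=1e-9)

    @pytest.mark.parametrize("shift", [(1, 0), (0, 2), (2, 3), (-2, 1), (3, -3)])
    def test_integer_translation_recovered(self, rng, shift):
        """Mean recovered flow within 0.25 px of an integer shift."""
        frame = make_speckle_frame(rng, shape=(80, 100))
        moved = translate_frame(frame, *shift)
        pts = [(r, c) for r in (30, 40, 50) for c in (40, 50, 60)]
        flow, valid = _track_pair(frame, moved, pts, m=15, pyramid_levels=3)
        assert valid.all()
        mean_flow = flow.mean(axis=0)
        assert mean_flow[0] == pytest.approx(shift[0], abs=0.25)
        assert mean_flow[1] == pytest.approx(shift[1], abs=0.25)

    def test_sinusoidal_phantom_tracked_within_tolerance(self):
        """Rigid sinusoidal translation, 3 px amplitude, 25 frames/cycle:
        mean tracked displacement matches the motion within 0.3 px RMS."""
        spec = PhantomSpec(
            image_size=(96, 144), band_center_row=44, band_curvature=6.0,
            band_thickness=10.0, band_col_margin=20.0,
            n_frames=50, breath_period=1.0, frame_interval=0.04,
            translation_amplitude_v=3.0, translation_amplitude_h=0.0,
            strain_amplitude=0.0, drift_rate=0.0, seed=5,
        )
        seq, truth = render_sequence(spec)
        rows, cols = np.nonzero(truth.mask0)
        sel = np.random.default_rng(0).choice(len(rows), size=60, replace=False)
        seeds = SeedPoints(
            coords=np.column_stack([rows[sel], cols[sel]]).astype(float),
            n_requested=60, seed=0,
        )
        tracked = track_sequence(seq, seeds, m=15)
        mean_v = np.array([
            (tracked.trajectories[t, tracked.valid_mask[t], 0]
             - tracked.trajectories[0, tracked.valid_mask[t], 0]).mean()
            for t in range(seq.n_frames)
        ])
        rms = np.sqrt(np.mean((mean_v - truth.translation_v) ** 2))
        assert rms < 0.3

    def test_forward_backward_consistency(self, small_phantom):
        """Tracking the reversed sequence returns points to their start:
        cumulative displacement of the reversed run negates the forward one
        within 0.3 px RMS."""
        _, seq, truth = small_phantom
        sub = seq.frames[:40]
        rows, cols = np.nonzero(truth.mask0)
        sel = np.random.default_rng(1).choice(len(rows), size=50, replace=False)
        pts = np.column_stack([rows[sel], cols[sel]]).astype(float)

        fwd_seq = FrameSequence(frames=sub, frame_interval=0.04)
        seeds = SeedPoints(coords=pts, n_requested=len(pts), seed=0)
        fwd = track_sequence(fwd_seq, seeds, m=15)
        end_pts = fwd.trajectories[-1][fwd.valid_mask[-1]]

        bwd_seq = FrameSequence(frames=sub[::-1].copy(), frame_interval=0.04)
        bwd_seeds = SeedPoints(coords=end_pts, n_requested=len(end_pts), seed=0)
        bwd = track_sequence(bwd_seq, bwd_seeds, m=15)

        fwd_disp = (end_pts - fwd.trajectories[0][fwd.valid_mask[-1]]).mean(axis=0)
        ok = bwd.valid_mask[-1]
        bwd_disp = (bwd.trajectories[-1][ok] - bwd.trajectories[0][ok]).mean(axis=0)
        assert np.sqrt(np.mean((fwd_disp + bwd_disp) ** 2)) < 0.3

    def test_noise_degrades_recovery_monotonically(self, rng):
        """Mean recovery error is non-decreasing in expectation as additive
        noise grows over sigma in {0, 5, 10, 20} gray levels."""
        sigmas = [0.0, 5.0, 10.0, 20.0]
        errors = {s: [] for s in sigmas}
        for seed in range(10):
            r = np.random.default_rng(seed)
            frame = make_speckle_frame(r, shape=(64, 96))
            moved = translate_frame(frame, 1.0, 2.0)
            pts = [(r0, c0) for r0 in (24, 32, 40) for c0 in (36, 48, 60)]
            for s in sigmas:
                noisy0 = frame + r.normal(0, s, frame.shape)
                noisy1 = moved + r.normal(0, s, frame.shape)
                flow, valid = _track_pair(noisy0, noisy1, pts, m=15)
                err = np.linalg.norm(flow[valid].mean(axis=0) - np.array([1.0, 2.0]))
                errors[s].append(err)
        means = [np.mean(errors[s]) for s in sigmas]
        assert all(b >= a - 1e-3 for a, b in zip(means[:-1], means[1:])), means


class TestGroups:
    def _tracked(self, pts, n_frames=3):
        seq_traj = np.tile(np.asarray(pts, dtype=float)[None], (n_frames, 1, 1))
        from diaflow import TrackedPoints

        return TrackedPoints(
            trajectories=seq_traj,
            valid_mask=np.ones((n_frames, len(pts)), dtype=bool),
            window_m=15,
        )

    def test_collinear_points_split_into_equal_adjacent_pairs(self):
        pts = [(10, 2 * i) for i in range(30)]
        tracked = assign_groups(self._tracked(pts), k=15)
        sizes = np.bincount(tracked.group_id)[1:]
        assert (sizes == 2).all()
        # contiguity: group of a point only depends on its column rank
        cols = np.array([p[1] for p in pts])
        order = np.argsort(cols)
        gids = tracked.group_id[order]
        assert (np.diff(gids) >= 0).all()

    def test_centroids_ordered_left_to_right(self, rng):
        pts = np.column_stack([rng.uniform(10, 20, 45), rng.uniform(0, 100, 45)])
        tracked = assign_groups(self._tracked(pts), k=15)
        cent = group_centroids(tracked)
        assert (np.diff(cent[0, :, 1]) > 0).all()

    def test_one_point_per_group_centroids_equal_points(self):
        pts = [(5.0, float(i * 3)) for i in range(15)]
        tracked = assign_groups(self._tracked(pts), k=15)
        cent = group_centroids(tracked)
        np.testing.assert_allclose(cent[0], np.asarray(pts))

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            assign_groups(self._tracked([(0, 0), (1, 1)]), k=15)

    def test_group_sizes_balanced(self, rng):
        pts = np.column_stack([rng.uniform(0, 30, 100), rng.uniform(0, 200, 100)])
        tracked = assign_groups(self._tracked(pts), k=15)
        sizes = np.bincount(tracked.group_id)[1:]
        assert set(sizes.tolist()) <= {6, 7}
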