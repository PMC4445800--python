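"""Differential translation estimation: hand-computed derivative values,
agreement with the brute-force SSD oracle, and the symmetry properties of
the normal-equation solve."""

import numpy as np
import pytest

from leafmotion import (
    BlobSceneSpec,
    ImageStack,
    compute_derivatives,
    estimate_translation,
    simulate_image_sequence,
    track_stack,
)
from leafmotion.synth import render_blob_frame

from _oracles import gaussian_mixture_pattern, ssd_grid_translation


class TestComputeDerivatives:
    def test_constant_frames_zero_everywhere(self):
        f = np.full((8, 8), 0.7)
        d = compute_derivatives(f, f)
        assert np.all(d.f_x == 0) and np.all(d.f_y == 0) and np.all(d.f_t == 0)
        assert d.f_x.shape == (7, 7)

    def test_horizontal_ramp(self):
        # two-tap derivative filter (0.5, -0.5) on f(x,y)=x gives 0.5 per px
        f = np.tile(np.arange(8, dtype=float), (6, 1))
        d = compute_derivatives(f, f)
        assert np.allclose(d.f_x, 0.5)
        assert np.allclose(d.f_y, 0.0)
        assert np.allclose(d.f_t, 0.0)

    def test_vertical_ramp(self):
        f = np.tile(np.arange(6, dtype=float)[:, None], (1, 8))
        d = compute_derivatives(f, f)
        assert np.allclose(d.f_y, 0.5)
        assert np.allclose(d.f_x, 0.0)

    def test_uniform_brightness_step(self):
        # temporal half-difference of a +c step is c/2 everywhere
        rng = np.random.default_rng(0)
        f0 = rng.uniform(0, 1, (10, 10))
        c = 0.25
        d = compute_derivatives(f0 + c, f0)
        assert np.allclose(d.f_t, c / 2)
        d0 = compute_derivatives(f0, f0)
        assert np.allclose(d.f_x, d0.f_x) and np.allclose(d.f_y, d0.f_y)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            compute_derivatives(np.zeros((4, 4)), np.zeros((4, 5)))


class TestEstimateTranslation:
    def test_degenerate_texture_flags_singular_matrix(self):
        d = compute_derivatives(np.full((10, 10), 0.5), np.full((10, 10), 0.5))
        vec = estimate_translation(d)
        assert not vec.condition_ok
        assert np.isnan(vec.v_x) and np.isnan(vec.v_y)

    def test_vertical_half_pixel_shift(self, blob_pair_factory):
        f0, f1 = blob_pair_factory(0.5)
        vec = estimate_translation(compute_derivatives(f1, f0))
        assert vec.condition_ok
        assert vec.v_y == pytest.approx(0.5, abs=0.05)
        assert vec.v_x == pytest.approx(0.0, abs=0.05)

    def test_diagonal_shift_matches_ssd_oracle(self, blob_scene):
        cy, cx = blob_scene.center_yx

        def render(dy, dx):
            return render_blob_frame(blob_scene, cy + dy, cx + dx)

        f0, f1 = render(0, 0), render(-0.4, 0.3)
        vec = estimate_translation(compute_derivatives(f1, f0))
        ody, odx = ssd_grid_translation(render, f1)
        assert vec.v_y == pytest.approx(ody, abs=0.05)
        assert vec.v_x == pytest.approx(odx, abs=0.05)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_subpixel_shifts_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        render = gaussian_mixture_pattern(rng)
        dy, dx = rng.uniform(-1, 1, size=2)
        f0, f1 = render(0, 0), render(dy, dx)
        vec = estimate_translation(compute_derivatives(f1, f0))
        ody, odx = ssd_grid_translation(render, f1)
        assert abs(vec.v_y - ody) < 0.05
        assert abs(vec.v_x - odx) < 0.05

    def test_time_reversal_antisymmetry_exact(self, blob_pair_factory):
        # swapping the frames flips f_t only, so the solve negates exactly
        f0, f1 = blob_pair_factory(0.7, -0.2)
        fwd = estimate_translation(compute_derivatives(f1, f0))
        rev = estimate_translation(compute_derivatives(f0, f1))
        assert abs(fwd.v_y + rev.v_y) < 1e-10
        assert abs(fwd.v_x + rev.v_x) < 1e-10

    def test_transpose_swaps_axes_exactly(self, blob_pair_factory):
        f0, f1 = blob_pair_factory(0.6, 0.25)
        v = estimate_translation(compute_derivatives(f1, f0))
        vt = estimate_translation(compute_derivatives(f1.T, f0.T))
        assert vt.v_x == pytest.approx(v.v_y, abs=1e-12)
        assert vt.v_y == pytest.approx(v.v_x, abs=1e-12)

    def test_brightness_offset_invariance(self, blob_pair_factory):
        f0, f1 = blob_pair_factory(0.5, 0.1)
        v = estimate_translation(compute_derivatives(f1, f0))
        vb = estimate_translation(compute_derivatives(f1 + 0.2, f0 + 0.2))
        assert abs(v.v_x - vb.v_x) < 1e-10
        assert abs(v.v_y - vb.v_y) < 1e-10

    def test_error_grows_beyond_small_motion_regime(self, blob_pair_factory):
        # the one-shot linearized solve degrades monotonically past ~2 px
        errs = []
        for shift in (0.5, 2.0, 3.5, 5.0):
            f0, f1 = blob_pair_factory(shift)
            v = estimate_translation(compute_derivatives(f1, f0))
            errs.append(abs(v.v_y - shift))
        assert errs == sorted(errs)
        assert errs[0] < 0.05 < errs[-1]

    def test_empty_and_tiny_roi_rejected(self, blob_pair_factory):
        f0, f1 = blob_pair_factory(0.5)
        d = compute_derivatives(f1, f0)
        with pytest.raises(ValueError, match="fewer than minimum"):
            estimate_translation(d, roi=(0, 0, 3, 3))
        with pytest.raises(ValueError, match="ROI"):
            estimate_translation(d, roi=(0, 0, 200, 200))


class TestTrackStack:
    def test_static_scene_yields_zero_motion(self):
        scene = BlobSceneSpec(frame_size=(48, 48), oscillation_amplitude=0.0,
                              duration=4.0, true_period=1.5)
        trace = track_stack(simulate_image_sequence(scene))
        assert np.allclose(trace.v_y_series, 0.0, atol=1e-12)
        assert np.allclose(trace.v_x_series, 0.0, atol=1e-12)
        assert not trace.interpolated.any()

    def test_oscillating_blob_velocity_is_sinusoidal(self):
        scene = BlobSceneSpec(true_period=24.0, oscillation_amplitude=6.0,
                              duration=48.0)
        trace = track_stack(simulate_image_sequence(scene))
        # position y(t) = y0 + A cos(w t) => per-step displacement is
        # y(t+dt) - y(t), a sinusoid with amplitude 2 A sin(w dt / 2)
        w = 2 * np.pi / 24.0
        dt = 1 / 3.0
        expected = 2 * 6.0 * np.sin(w * dt / 2) * -np.sin(w * trace.times)
        assert np.allclose(trace.v_y_series, expected, atol=0.02)
        assert len(trace) == len(simulate_image_sequence(scene)) - 1

    def test_reversed_frame_order_negates_series(self):
        scene = BlobSceneSpec(true_period=24.0, duration=48.0)
        stack = simulate_image_sequence(scene)
        rev = ImageStack(stack.frames[::-1].copy(), stack.sampling_interval,
                         list(reversed(stack.source_ids)))
        fwd_trace = track_stack(stack)
        rev_trace = track_stack(rev)
        assert np.allclose(fwd_trace.v_y_series + rev_trace.v_y_series[::-1],
                           0.0, atol=0.02)

    def test_ill_conditioned_pairs_interpolated_and_flagged(self):
        scene = BlobSceneSpec(frame_size=(48, 48), oscillation_amplitude=1.0,
                              true_period=8.0, duration=16.0)
        stack = simulate_image_sequence(scene)
        frames = stack.frames.copy()
        frames[3] = 0.5  # one featureless frame mid-sequence
        frames[4] = 0.5
        broken = ImageStack(frames, stack.sampling_interval, list(stack.source_ids))
        trace = track_stack(broken)
        assert trace.interpolated[3]  # the constant-constant pair
        assert np.all(np.isfinite(trace.v_y_series))

    def test_midpoint_time_grid(self):
        scene = BlobSceneSpec(frame_size=(48, 48), oscillation_amplitude=0.0,
                              duration=2.0, true_period=0.9)
        trace = track_stack(simulate_image_sequence(scene))
        assert trace.times[0] == pytest.approx(1 / 6)
        assert np.allclose(np.diff(trace.times), 1 / 3)
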