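"""Six-step tracker: per-step hand oracles, round trips, invariances."""

import numpy as np
import pytest

from fiberkin import synth
from fiberkin.io import ImageSequence
from fiberkin.tracking import (
    TrackerParams, column_peak_subpixel, column_width_halfmax,
    estimate_background, reject_inconsistent, smooth_and_extrapolate,
    smooth_frame, subpixel_offset, track_sequence,
)


class TestBackground:
    def test_uniform_movie_degenerate(self):
        seq = ImageSequence(np.full((3, 8, 8), 10.0))
        model, sub = estimate_background(seq)
        assert (model.i0, model.i1, model.dev) == (10.0, 10.0, 0.0)
        assert np.all(sub.data == 0)

    def test_constructed_histogram(self):
        # background {90: 25%, 100: 50%, 110: 25%} plus fiber at 1000
        bg = np.array([90.0] * 25 + [100.0] * 50 + [110.0] * 25)
        data = np.concatenate([bg, [1000.0, 1000.0]]).reshape(1, 2, 51)
        model, sub = estimate_background(ImageSequence(data))
        assert model.i0 == 100 and model.i1 == 90 and model.dev == 10
        assert np.all(sub.data[data == 1000.0] == 890.0)
        assert np.all(sub.data[data < 1000.0] == 0.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        data = np.rint(rng.normal(100, 5, (4, 16, 16)))
        data[:, 8, :] = 500
        _, a = estimate_background(ImageSequence(data))
        _, b = estimate_background(ImageSequence(data + 7))
        assert np.array_equal(a.data, b.data)


class TestSmoothFrame:
    def test_uniform_unchanged(self):
        frame = np.full((20, 20), 3.0)
        assert np.allclose(smooth_frame(frame, 3.5, 1.9), 3.0)

    def test_impulse_second_moments(self):
        frame = np.zeros((81, 81))
        frame[40, 40] = 1.0
        out = smooth_frame(frame, sigma_x=3.5, sigma_y=1.9)
        ys, xs = np.mgrid[0:81, 0:81]
        var_x = np.sum(out * (xs - 40) ** 2) / out.sum()
        var_y = np.sum(out * (ys - 40) ** 2) / out.sum()
        assert var_x == pytest.approx(3.5**2, rel=0.01)
        assert var_y == pytest.approx(1.9**2, rel=0.01)
        assert out.sum() == pytest.approx(1.0, rel=1e-3)


class TestColumnPeak:
    @pytest.mark.parametrize("col,offset", [
        ([0, 2, 5, 2, 0], 0.0),                    # symmetric peak
        ([0, 2, 5, 4, 0], (4 - 2) / (20 - 4 - 8)),  # hand value 0.25
    ])
    def test_subpixel_offset(self, col, offset):
        peak = column_peak_subpixel(np.array(col, float))
        assert peak.valid
        assert peak.y_raw - peak.y0 == pytest.approx(offset)

    def test_plateau_degenerate_denominator(self):
        # exact plateau (5, 5, 5): denominator 0 -> offset 0 by convention
        assert subpixel_offset(5.0, 5.0, 5.0) == 0.0
        assert subpixel_offset(2.0, 5.0, 4.0) == pytest.approx(0.25)
        assert subpixel_offset(2.0, 5.0, 2.0) == 0.0

    def test_all_zero_invalid(self):
        assert not column_peak_subpixel(np.zeros(5)).valid

    def test_boundary_argmax_invalid(self):
        assert not column_peak_subpixel(np.array([5.0, 1.0, 0.0])).valid

    def test_clamped_to_unit_offset(self):
        peak = column_peak_subpixel(np.array([0.0, 1.0, 10.0, 9.99, 0.0]))
        assert abs(peak.y_raw - peak.y0) <= 1.0


class TestColumnWidth:
    def test_hand_thresholding(self):
        w, valid = column_width_halfmax(np.array([0, 0, 2, 6, 8, 6, 2, 0.0]))
        assert w == 3 and valid

    def test_two_objects_rejected(self):
        col = np.zeros(20)
        col[2:5] = 8.0    # object 1
        col[11:14] = 7.0  # object 2, above half max of 8
        w, valid = column_width_halfmax(col)
        assert w == 12 and not valid

    def test_single_pixel_peak(self):
        col = np.zeros(9)
        col[4] = 5.0
        assert column_width_halfmax(col) == (1, True)

    def test_zero_column_invalid(self):
        w, valid = column_width_halfmax(np.zeros(5))
        assert np.isnan(w) and not valid


class TestSmoothExtrapolate:
    def test_constant_fixed_point(self):
        y_raw = np.full(50, 7.5)
        valid = np.zeros(50, bool)
        valid[10:30] = True
        y = smooth_and_extrapolate(y_raw, valid)
        assert np.allclose(y, 7.5)

    def test_maximum_principle(self):
        rng = np.random.default_rng(1)
        y_raw = rng.uniform(3, 9, 80)
        valid = rng.random(80) < 0.6
        y = smooth_and_extrapolate(y_raw, valid)
        assert y.min() >= y_raw[valid].min() - 1e-9
        assert y.max() <= y_raw[valid].max() + 1e-9

    def test_matches_brute_force_iteration(self):
        rng = np.random.default_rng(2)
        y_raw = rng.uniform(0, 10, 60)
        valid = rng.random(60) < 0.5
        y = smooth_and_extrapolate(y_raw, valid, 5.8, n_iter=300)

        from scipy.ndimage import gaussian_filter1d
        z = np.full(60, y_raw[valid].mean())
        z[valid] = y_raw[valid]
        den = gaussian_filter1d(np.ones(60), 5.8, mode="constant")
        sups = []
        for _ in range(300):
            z_prev = z.copy()
            z[valid] = y_raw[valid]
            z = gaussian_filter1d(z, 5.8, mode="constant") / den
            sups.append(np.max(np.abs(z - z_prev)))
            if sups[-1] < 1e-6:
                break
        assert np.allclose(y, z, atol=1e-5)
        # successive-iterate sup-norm decreases monotonically
        assert all(b <= a + 1e-12 for a, b in zip(sups, sups[1:]))

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError, match="untracked"):
            smooth_and_extrapolate(np.zeros(10), np.zeros(10, bool))


class TestRejectInconsistent:
    def test_identity_keeps_domain(self):
        y = np.linspace(0, 5, 20)
        valid = np.ones(20, bool)
        assert np.array_equal(reject_inconsistent(y, y, valid), valid)

    def test_boundary_is_strict(self):
        y = np.zeros(3)
        y_raw = np.array([0.0, 1.0, 1.0 + 1e-9])
        keep = reject_inconsistent(y, y_raw, np.ones(3, bool), 1.0)
        assert keep.tolist() == [True, True, False]

    def test_outlier_column_removed_and_curve_unaffected(self):
        # one column displaced 5 px from a smooth neighbourhood
        n = 120
        y_raw = np.full(n, 20.0)
        y_raw[60] += 5.0
        valid = np.ones(n, bool)
        y1 = smooth_and_extrapolate(y_raw, valid)
        keep = reject_inconsistent(y1, y_raw, valid)
        assert not keep[60] and keep.sum() == n - 1
        y2 = smooth_and_extrapolate(y_raw, keep)
        # oracle: tracking with the outlier column deleted outright
        oracle = smooth_and_extrapolate(np.full(n, 20.0), keep)
        assert np.max(np.abs(y2 - oracle)) < 0.2


class TestTrackSequence:
    def test_static_noiseless_subpixel(self, static_fiber):
        spec, seq, y_um = static_fiber
        trace = track_sequence(seq)
        assert trace.tracked.all()
        err = trace.y - y_um / spec.pixel_size
        assert np.sqrt(np.mean(err**2)) < 0.05

    def test_snr5_tolerance(self):
        spec = synth.FiberMovieSpec(
            n_frames=20, width_px=300, fiber_peak=400.0,
            background_noise_sd=80.0, oscillation_amplitude=0.1, seed=2)
        seq, y_um = synth.make_fiber_movie(spec)
        trace = track_sequence(seq)
        err = trace.y - y_um / spec.pixel_size
        assert np.sqrt(np.nanmean(err**2)) < 0.3

    def test_vertical_shift_equivariance(self, static_fiber):
        spec, seq, _ = static_fiber
        base = track_sequence(seq)
        shifted = seq.with_data(np.roll(seq.data, 3, axis=1))
        tr = track_sequence(shifted)
        assert np.allclose(tr.y, base.y + 3, atol=1e-6)

    def test_intensity_scale_invariance(self, static_fiber):
        _, seq, _ = static_fiber
        base = track_sequence(seq)
        tr = track_sequence(seq.with_data(seq.data * 2.0))
        assert np.allclose(tr.y, base.y, atol=1e-9)

    def test_blob_robustness_outside_blob(self):
        spec = synth.FiberMovieSpec(n_frames=6, width_px=200,
                                    background_noise_sd=0.0,
                                    oscillation_amplitude=0.0, seed=5)
        seq, y_um = synth.make_fiber_movie(spec)
        data = seq.data.copy()
        ys, xs = np.mgrid[0:spec.height_px, 0:spec.width_px]
        blob = spec.fiber_peak * np.exp(
            -((ys - 20) ** 2 + (xs - 100) ** 2) / (2 * 4.0**2))
        data += blob[None]
        tr = track_sequence(seq.with_data(data))
        oracle = track_sequence(seq)
        outside = np.abs(np.arange(spec.width_px) - 100) > 15
        diff = np.abs(tr.y[:, outside] - oracle.y[:, outside])
        assert np.nanmax(diff) < 0.5

    def test_trace_invariants(self, static_fiber):
        _, seq, _ = static_fiber
        tr = track_sequence(seq)
        p = tr.params
        assert np.all(tr.width[tr.valid] < p.width_limit)
        dev = np.abs(tr.y - tr.y_raw)
        assert np.nanmax(dev[tr.valid]) <= p.consistency_tol + 1e-9
        assert np.all(np.isfinite(tr.y[tr.tracked]))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            TrackerParams(sigma_x=-1)
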