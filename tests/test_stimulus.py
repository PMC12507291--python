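"""Stimulus, saccade, target-schedule and renderer tests."""

import numpy as np
import pytest
import scipy.fft

from streakvision.exceptions import (ParameterError, RenderError,
                                     SchedulingError)
from streakvision.stimulus import (FULL_SCALE, make_noise_patch,
                                   render_retinal_movie,
                                   retinal_rotation_label,
                                   schedule_target_motion, simulate_trial,
                                   synthesize_saccade)


def radial_power_profile(patch):
    """Radially averaged power spectrum (cpd bins) of a patch."""
    n = patch.size_px
    p = np.abs(scipy.fft.fft2(patch.pixels)) ** 2
    f = np.hypot(*np.meshgrid(scipy.fft.fftfreq(n, d=patch.pitch),
                              scipy.fft.fftfreq(n, d=patch.pitch)))
    bins = np.linspace(0, f.max(), 24)
    idx = np.digitize(f.ravel(), bins)
    prof = np.array([p.ravel()[idx == i].mean() if np.any(idx == i) else 0.0
                     for i in range(1, len(bins))])
    centers = 0.5 * (bins[1:] + bins[:-1])
    return centers, prof


class TestNoisePatch:
    def test_measured_cutoffs_match_nominal(self):
        """-3 dB points of the radial power spectrum sit near 0.33/1.02 cpd."""
        patch = make_noise_patch(seed=7, size_px=51)
        f, p = radial_power_profile(patch)
        half = p.max() / 2.0
        above = np.nonzero(p >= half)[0]
        lo, hi = f[above[0]], f[above[-1]]
        assert lo == pytest.approx(0.33, rel=0.5)
        assert hi == pytest.approx(1.02, rel=0.20)
        # out-of-band power is at least 3 dB below the peak
        out_band = (f < 0.2) | (f > 1.6)
        assert np.all(p[out_band & (p > 0)] <= p.max() / 2.0)

    def test_normalisation_and_bounds(self):
        patch = make_noise_patch(seed=3)
        assert np.abs(patch.pixels).max() <= 1.0
        # peak contrast reaches 1 before the aperture; with an aperture SD
        # of 0.56 dva the surviving peak still exceeds ~0.3
        assert np.abs(patch.pixels).max() > 0.3

    def test_zero_amplitude_gives_zero_patch(self):
        patch = make_noise_patch(seed=5, amplitude=0.0)
        assert np.all(patch.pixels == 0)

    def test_seed_reproducibility_and_decorrelation(self):
        a = make_noise_patch(seed=12)
        b = make_noise_patch(seed=12)
        c = make_noise_patch(seed=13)
        assert np.array_equal(a.pixels, b.pixels)
        r = np.corrcoef(a.pixels.ravel(), c.pixels.ravel())[0, 1]
        assert abs(r) < 0.5

    @pytest.mark.parametrize("kwargs", [
        dict(size_px=50), dict(cutoff_hi=20.0), dict(cutoff_lo=-0.1),
        dict(cutoff_lo=1.2, cutoff_hi=0.4),
    ])
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ParameterError):
            make_noise_patch(seed=1, **kwargs)


class TestSaccade:
    def test_mean_saccade_peak_velocity_in_observed_range(self):
        s = synthesize_saccade(amplitude=17.6, duration=0.0536)
        assert 400.0 <= s.peak_velocity <= 650.0

    def test_displacement_equals_amplitude(self):
        s = synthesize_saccade(amplitude=12.3, duration=0.05)
        disp = s.gaze[s.offset_idx, 0] - s.gaze[s.onset_idx, 0]
        assert disp == pytest.approx(12.3, abs=1e-6)

    def test_gaze_constant_outside_saccade(self):
        s = synthesize_saccade(amplitude=10.0, duration=0.04)
        assert np.all(s.gaze[:s.onset_idx + 1] == s.gaze[0])
        assert np.all(s.gaze[s.offset_idx:] == s.gaze[-1])

    def test_zero_amplitude_is_constant_gaze(self):
        s = synthesize_saccade(amplitude=0.0, duration=0.05)
        assert np.all(s.gaze == s.gaze[0])
        assert s.peak_velocity == 0.0

    def test_vertical_bias_reached_at_offset(self):
        s = synthesize_saccade(amplitude=17.6, vertical_bias=0.15)
        assert s.gaze[s.offset_idx, 1] - s.gaze[s.onset_idx, 1] == \
            pytest.approx(0.15, abs=1e-9)

    def test_velocity_profile_unimodal(self):
        s = synthesize_saccade(amplitude=17.6, duration=0.0536)
        v = np.linalg.norm(np.diff(s.gaze, axis=0), axis=1)
        peak = np.argmax(v)
        assert np.all(np.diff(v[:peak]) >= -1e-12)
        assert np.all(np.diff(v[peak:]) <= 1e-12)

    def test_leftward_direction_mirrors(self):
        s = synthesize_saccade(amplitude=8.0, direction="left")
        assert s.gaze[-1, 0] - s.gaze[0, 0] == pytest.approx(-8.0)


class TestTargetSchedule:
    def test_motion_spans_36_frames_at_1440(self):
        s = synthesize_saccade(rate=1440.0)
        t = schedule_target_motion("upward", "present", s)
        n = t.motion_offset_idx - t.motion_onset_idx + 1
        assert n == 36 == round(0.025 * 1440)

    def test_static_is_constant_and_visible(self):
        s = synthesize_saccade()
        t = schedule_target_motion("static", "present", s)
        assert np.all(t.visible)
        assert np.all(t.position == t.position[0])

    def test_absent_blanks_and_jumps_to_endpoint(self):
        s = synthesize_saccade(rate=1440.0)
        t = schedule_target_motion("upward", "absent", s,
                                   start_position=(18.25, 0.0))
        k = t.motion_onset_idx
        assert np.allclose(t.position[k + 35], (18.25, 6.6))
        assert not t.visible[k:k + 35].any()
        assert t.visible[k + 35]

    def test_present_moves_at_constant_velocity(self):
        s = synthesize_saccade(rate=1440.0)
        t = schedule_target_motion("outward", "present", s)
        seg = t.position[t.motion_onset_idx:t.motion_offset_idx + 1]
        steps = np.diff(seg, axis=0)
        assert np.allclose(steps, steps[0])
        assert np.linalg.norm(seg[-1] - seg[0]) == pytest.approx(6.6)

    def test_motion_strictly_inside_saccade(self):
        s = synthesize_saccade(rate=1440.0)
        t = schedule_target_motion("downward", "present", s)
        assert t.motion_onset_idx > s.onset_idx
        assert t.motion_offset_idx < s.offset_idx

    def test_overlong_motion_raises_scheduling_error(self):
        s = synthesize_saccade(duration=0.0536)
        with pytest.raises(SchedulingError):
            schedule_target_motion("upward", "present", s,
                                   start_latency=0.040)


class TestRenderer:
    def test_static_gaze_static_target_frames_identical(self):
        patch = make_noise_patch(seed=2, size_px=25, pitch=0.124)
        s = synthesize_saccade(amplitude=0.0, duration=0.05, rate=240.0,
                               pre_time=0.01, post_time=0.01)
        t = schedule_target_motion("static", "present", s,
                                   start_position=(3.0, 1.0))
        m = render_retinal_movie(patch, s, t, extent=(-8, 8, -6, 6))
        assert np.all(m.frames == m.frames[0])
        assert m.frames[0].any()

    def test_retinal_position_is_target_minus_gaze(self):
        """Center of mass of |frame| tracks target - gaze per frame."""
        patch = make_noise_patch(seed=2, size_px=25, pitch=0.124)
        s = synthesize_saccade(amplitude=5.0, duration=0.05, rate=240.0,
                               pre_time=0.01, post_time=0.01)
        t = schedule_target_motion("upward", "present", s,
                                   start_position=(5.5, 0.0),
                                   distance=2.0, start_latency=0.008)
        m = render_retinal_movie(patch, s, t, extent=(-8, 8, -6, 6))
        for i in range(0, m.n_frames, 7):
            expect = t.position[i] - s.gaze[i]
            w = np.abs(m.frames[i])
            ys, xs = np.mgrid[0:w.shape[0], 0:w.shape[1]]
            cx = (w * xs).sum() / w.sum()
            cy = (w * ys).sum() / w.sum()
            row, col = m.retinal_to_px(expect)
            assert abs(cx - col) < 0.7 and abs(cy - row) < 0.7

    def test_energy_conserved_across_subpixel_shifts(self):
        patch = make_noise_patch(seed=2, size_px=25, pitch=0.124)
        s = synthesize_saccade(amplitude=5.0, duration=0.05, rate=240.0,
                               pre_time=0.01, post_time=0.01)
        t = schedule_target_motion("static", "present", s,
                                   start_position=(5.5, 0.0))
        m = render_retinal_movie(patch, s, t, extent=(-8, 8, -6, 6))
        sums = np.abs(m.frames).sum(axis=(1, 2))
        assert sums.std() / sums.mean() < 0.02

    def test_out_of_canvas_raises_naming_frame(self):
        patch = make_noise_patch(seed=2, size_px=25, pitch=0.124)
        s = synthesize_saccade(amplitude=12.0, duration=0.05, rate=240.0,
                               pre_time=0.0, post_time=0.01)
        t = schedule_target_motion("static", "present", s,
                                   start_position=(5.0, 0.0))
        with pytest.raises(RenderError, match="frame"):
            render_retinal_movie(patch, s, t, extent=(-3, 8, -6, 6))


class TestRotationLabel:
    def test_four_combinations_give_two_of_each(self):
        labels = {(s, t): retinal_rotation_label(s, t)
                  for s in ("left", "right") for t in ("upward", "downward")}
        assert sorted(labels.values()).count("cw") == 2
        assert sorted(labels.values()).count("ccw") == 2

    def test_flipping_both_preserves_flipping_one_flips(self):
        base = retinal_rotation_label("right", "upward")
        assert retinal_rotation_label("left", "downward") == base
        assert retinal_rotation_label("left", "upward") != base
        assert retinal_rotation_label("right", "downward") != base

    def test_non_vertical_target_undefined(self):
        assert retinal_rotation_label("right", "static") == "undefined"
        assert retinal_rotation_label("left", "outward") == "undefined"


class TestSimulateTrial:
    def test_bit_reproducible_under_seed(self):
        a = simulate_trial("upward", "present", seed=4,
                           scale=_small_scale())
        b = simulate_trial("upward", "present", seed=4,
                           scale=_small_scale())
        assert np.array_equal(a.movie.frames, b.movie.frames)

    def test_outward_minimum_retinal_speed_far_below_static(self):
        speeds = {}
        for d in ("outward", "static"):
            sp = [simulate_trial(d, "present", seed=s, scale=_small_scale()
                                 ).min_retinal_speed() for s in range(5)]
            speeds[d] = np.mean(sp)
        assert speeds["outward"] < 0.5 * speeds["static"]

    def test_motion_frame_count_rescales_with_rate(self):
        t = simulate_trial("upward", "present", seed=1, scale=_small_scale())
        n = t.target.motion_offset_idx - t.target.motion_onset_idx + 1
        assert n == round(0.025 * t.movie.rate)


def _small_scale():
    from streakvision.stimulus import SimulationScale
    return SimulationScale(pitch=0.124, rate=240.0)
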