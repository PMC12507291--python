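"""Energy, lowpass pooling and delayed divisive normalization."""

import numpy as np
import pytest

from streakvision.exceptions import ParameterError
from streakvision.normalization import (NormalizationSpec, delayed_normalize,
                                        energy, lowpass_pool, run_model,
                                        _pool_matrix)
from streakvision.spatial import BankSpec, build_bank
from streakvision.stimulus import RetinalMovie

SF_SET = (0.25, 0.4, 0.63, 1.0, 1.59, 2.52, 4.0)
ORI_SET = (-67.5, -45.0, -22.5, 0.0, 22.5, 45.0, 67.5, 90.0)


class TestEnergy:
    def test_three_four_five(self):
        rst = np.zeros((1, 1, 2, 1, 1, 1))
        rst[0, 0, 0] = 3.0
        rst[0, 0, 1] = 4.0
        assert energy(rst)[0, 0, 0, 0, 0] == 25.0

    def test_nonnegative_for_random_input(self, rng):
        rst = rng.standard_normal((2, 3, 2, 4, 5, 5))
        assert np.all(energy(rst) >= 0)

    def test_missing_phase_axis_rejected(self):
        with pytest.raises(ParameterError):
            energy(np.zeros((2, 3, 1, 4, 5, 5)))

    def test_quadrature_energy_of_drifting_grating_is_flat(self):
        """A drifting grating through a quadrature pair yields an energy
        time course with small ripple (phase invariance)."""
        bank = build_bank(BankSpec(), pitch=0.124)
        k = bank[(1.0, 90.0)]  # vertical stripes, horizontal drift
        n, rate, speed = 48, 240.0, 2.0
        ax = (np.arange(81) - 40) * 0.124
        X, Y = np.meshgrid(ax, ax)
        frames = np.stack([np.cos(2 * np.pi * 1.0 * (X - speed * t / rate))
                           for t in range(n)]).astype(np.float64)
        from streakvision.spatial import convolve_frames
        r = convolve_frames(frames, k.weights)[:, 40, 40]
        e = np.abs(r) ** 2
        e = e[10:]  # settled part
        assert e.std() / e.mean() < 0.1


class TestPooling:
    def test_pool_weights_peak_at_zero_distance(self):
        w = _pool_matrix(SF_SET, ORI_SET, NormalizationSpec())
        for i in range(7):
            for j in range(8):
                row = w[i, j]
                assert row[i, j] == row.max()

    def test_pool_restricted_to_two_cells(self):
        w = _pool_matrix(SF_SET, ORI_SET, NormalizationSpec())
        # SF four steps away is outside the +/-2 pool
        assert w[0, 0, 3, 0] == 0.0
        assert w[0, 0, 2, 0] > 0.0
        # orientation wraps: -67.5 and 90 are adjacent channels
        assert w[0, 0, 0, 7] > 0.0

    def test_three_channel_toy_matches_hand_weights(self):
        """Hand-computed Gaussian weights on a 3-SF, 1-orientation toy.

        Spatially uniform input on a grid wide enough that the centre
        pixel sees the full unit-sum blur kernel; pitch 1.0 keeps the
        0.5 dva blur inside a 2-pixel margin.
        """
        sfs, oris = (0.5, 1.0, 2.0), (0.0,)
        spec = NormalizationSpec()
        re = np.zeros((3, 1, 1, 7, 7), dtype=np.float64)
        re[:, 0, 0] = np.array([1.0, 2.0, 4.0])[:, None, None]
        rlp = lowpass_pool(re, spec, rate=240.0, pitch=1.0,
                           sf_set=sfs, ori_set=oris)
        # steady state not reached after 1 sample; undo the temporal
        # filter gain (1 - a) analytically
        a = np.exp(-1.0 / (spec.tau_n * 240.0))
        w = np.exp(-np.array([0.0, 1.0, 2.0]) ** 2 / 2.0)  # octave distances
        expect0 = (w[0] * 1 + w[1] * 2 + w[2] * 4) / w.sum() * (1 - a)
        assert rlp[0, 0, 0, 3, 3] == pytest.approx(expect0, rel=1e-9)

    def test_literal_printed_pool_form_is_available_and_differs(self):
        """The as-printed (non-Gaussian) pooling weight is retained for
        sensitivity analysis; it weights distant channels more than the
        channel itself and so differs from the Gaussian pool."""
        spec_g = NormalizationSpec()
        spec_l = NormalizationSpec(literal_printed_pool=True)
        wg = _pool_matrix(SF_SET, ORI_SET, spec_g)
        wl = _pool_matrix(SF_SET, ORI_SET, spec_l)
        assert wl.shape == wg.shape
        assert not np.allclose(wg, wl)
        # still valid row-normalised weights
        assert np.allclose(wl.reshape(56, 56).sum(axis=1), 1.0)

    def test_constant_input_unit_steady_state_gain(self):
        spec = NormalizationSpec(tau_n=0.01)
        re = np.ones((1, 1, 200, 7, 7), dtype=np.float32)
        rlp = lowpass_pool(re, spec, rate=1000.0, pitch=1.0,
                           sf_set=(1.0,), ori_set=(0.0,))
        assert rlp[0, 0, -1, 3, 3] == pytest.approx(1.0, abs=1e-3)


class TestDelayedNormalize:
    def test_zero_energy_zero_output(self):
        spec = NormalizationSpec()
        re = np.zeros((1, 1, 2, 2, 2))
        assert not delayed_normalize(re, re, spec).any()

    def test_steady_state_closed_form(self):
        """R_E = R_LP = 1 gives 1 / (1 + 0.07^1.4)."""
        spec = NormalizationSpec()
        re = np.ones((1, 1, 1, 1, 1))
        rn = delayed_normalize(re, re.copy(), spec)
        assert rn[0, 0, 0, 0, 0] == pytest.approx(
            1.0 / (1.0 + 0.07 ** 1.4), rel=1e-6)
        assert 1.0 / (1.0 + 0.07 ** 1.4) == pytest.approx(0.976, abs=5e-4)

    def test_monotone_in_semisaturation(self, rng):
        re = rng.random((2, 2, 3, 4, 4)).astype(np.float64)
        rlp = rng.random((2, 2, 3, 4, 4)).astype(np.float64)
        a = delayed_normalize(re, rlp, NormalizationSpec(sigma_semi=0.07))
        b = delayed_normalize(re, rlp, NormalizationSpec(sigma_semi=0.14))
        assert np.all(b <= a + 1e-12)

    def test_negative_input_rejected(self):
        spec = NormalizationSpec()
        with pytest.raises(ParameterError):
            delayed_normalize(np.array([[[[[-1.0]]]]]),
                              np.array([[[[[1.0]]]]]), spec)

    def test_normalization_preserves_zero_set(self, rng):
        re = rng.random((1, 2, 3, 4, 4))
        re[re < 0.5] = 0.0
        rlp = rng.random((1, 2, 3, 4, 4))
        rn = delayed_normalize(re, rlp, NormalizationSpec())
        assert np.array_equal(rn == 0, re == 0)


class TestStepDynamics:
    def test_step_input_transient_exceeds_sustained(self):
        """A sustained stimulus drives an onset transient followed by a
        lower sustained plateau (delayed normalization signature)."""
        spec = NormalizationSpec(tau_n=0.05)
        t_n = 400
        re = np.zeros((1, 1, t_n, 3, 3), dtype=np.float32)
        re[:, :, 20:] = 1.0
        rlp = lowpass_pool(re, spec, rate=1000.0, pitch=1.0,
                          sf_set=(1.0,), ori_set=(0.0,))
        rn = delayed_normalize(re, rlp, spec)
        series = rn[0, 0, :, 1, 1]
        assert series.max() > 1.5 * series[-1]
        assert np.argmax(series) < 60  # transient right after onset


class TestRunModel:
    def _tiny_setup(self):
        spec = BankSpec(sf_set=(0.63, 1.0), ori_set=(0.0, 90.0))
        bank = build_bank(spec, pitch=0.124)
        rng = np.random.default_rng(0)
        frames = np.zeros((10, 32, 32), dtype=np.float32)
        frames[3:, 12:20, 12:20] = rng.standard_normal((8, 8)).astype(
            np.float32)
        movie = RetinalMovie(frames=frames, pitch=0.124, rate=240.0,
                             extent=(-2, 2, -2, 2))
        kernels = [np.array([0.5, 0.3, -0.1]), np.array([0.6, 0.1])]
        return bank, movie, kernels

    def test_zero_movie_zero_output(self):
        bank, movie, kernels = self._tiny_setup()
        movie.frames = np.zeros_like(movie.frames)
        resp = run_model(movie, bank, kernels)
        assert not resp.rn.any()

    def test_matches_straight_line_reimplementation(self):
        """Five-stage miniature pipeline equals an independent
        step-by-step reimplementation (1e-8 relative)."""
        bank, movie, kernels = self._tiny_setup()
        spec = NormalizationSpec()
        resp = run_model(movie, bank, kernels, spec=spec, precision="double")
        expect = _straight_line_pipeline(movie, bank, kernels, spec)
        scale = np.abs(expect).max()
        assert np.max(np.abs(resp.rn - expect)) < 1e-8 * scale

    def test_normalization_keeps_peak_ordering_of_transients(self):
        """For brief transients, R_N peak ordering follows R_E peak
        ordering (transients are largely unaffected by normalization)."""
        bank, movie, kernels = self._tiny_setup()
        resp = run_model(movie, bank, kernels, keep_intermediates=True)
        re_peaks = resp.re.max(axis=(2, 3, 4)).ravel()
        rn_peaks = resp.rn.max(axis=(2, 3, 4)).ravel()
        assert np.array_equal(np.argsort(re_peaks), np.argsort(rn_peaks))


def _straight_line_pipeline(movie, bank, kernels, spec):
    """Independent reimplementation: direct convolutions, explicit
    exponential kernel, explicit Gaussian taps, explicit pooling."""
    import scipy.signal

    frames = np.asarray(movie.frames, dtype=np.float64)
    t, hgt, wid = frames.shape
    sfs, oris = list(bank.sf_set), list(bank.ori_set)
    S, O = len(sfs), len(oris)

    re = np.zeros((S, O, t, hgt, wid))
    for i, theta in enumerate(sfs):
        hk = np.asarray(kernels[i], dtype=np.float64)
        for j, omega in enumerate(oris):
            k = bank[(theta, omega)]
            resp_e = np.stack([scipy.signal.convolve2d(
                f, k.even, mode="same", boundary="fill") for f in frames])
            resp_o = np.stack([scipy.signal.convolve2d(
                f, k.odd, mode="same", boundary="fill") for f in frames])
            filt_e = np.zeros_like(resp_e)
            filt_o = np.zeros_like(resp_o)
            for ti in range(t):
                for s in range(min(ti + 1, len(hk))):
                    filt_e[ti] += hk[s] * resp_e[ti - s]
                    filt_o[ti] += hk[s] * resp_o[ti - s]
            re[i, j] = filt_e ** 2 + filt_o ** 2

    # temporal lowpass: explicit normalised exponential recursion
    a = np.exp(-1.0 / (spec.tau_n * movie.rate))
    rl = np.zeros_like(re)
    rl[:, :, 0] = (1 - a) * re[:, :, 0]
    for ti in range(1, t):
        rl[:, :, ti] = (1 - a) * re[:, :, ti] + a * rl[:, :, ti - 1]

    # spatial lowpass: explicit Gaussian taps (zero outside), shift-sum
    sd = spec.gl_sd / movie.pitch
    radius = int(2.5 * sd + 0.5)
    offs = np.arange(-radius, radius + 1)
    g = np.exp(-offs.astype(float) ** 2 / (2 * sd ** 2))
    g /= g.sum()

    def shift2(a, o, axis):
        out = np.zeros_like(a)
        src = [slice(None)] * a.ndim
        dst = [slice(None)] * a.ndim
        if o >= 0:
            src[axis] = slice(o, None)
            dst[axis] = slice(None, a.shape[axis] - o)
        else:
            src[axis] = slice(None, o)
            dst[axis] = slice(-o, None)
        out[tuple(dst)] = a[tuple(src)]
        return out

    blurred = np.zeros_like(rl)
    for i in range(S):
        for j in range(O):
            tmp = np.zeros((t, hgt, wid))
            for o, w in zip(offs, g):
                tmp += w * shift2(rl[i, j], o, axis=1)
            out = np.zeros((t, hgt, wid))
            for o, w in zip(offs, g):
                out += w * shift2(tmp, o, axis=2)
            blurred[i, j] = out

    # channel pooling with explicit wrapped Gaussian weights; each
    # channel enters the pool once, circular index distance <= radius
    rlp = np.zeros_like(re)
    for i in range(S):
        for j in range(O):
            wsum = 0.0
            acc = np.zeros((t, hgt, wid))
            for ii in range(S):
                if abs(ii - i) > spec.pool_radius:
                    continue
                d_oct = np.log2(sfs[i] / sfs[ii])
                for jj in range(O):
                    dj = abs(jj - j)
                    if min(dj, O - dj) > spec.pool_radius:
                        continue
                    d_ori = (oris[j] - oris[jj] + 90.0) % 180.0 - 90.0
                    w = np.exp(-(d_oct ** 2 / (2 * spec.sigma_p_theta ** 2)
                                 + d_ori ** 2 / (2 * spec.sigma_p_omega ** 2)))
                    acc += w * blurred[ii, jj]
                    wsum += w
            rlp[i, j] = acc / wsum
    n = spec.exponent
    return re ** n / (spec.sigma_semi ** n + rlp ** n)
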