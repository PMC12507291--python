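"""Quadrature energy and delayed divisive normalization.

Even/odd spatiotemporal responses are squared and summed into a
phase-invariant energy R_E, which is then divisively normalised by a
delayed copy of itself: R_E is lowpass filtered in time (exponential,
time constant tau), blurred in space (Gaussian, SD 0.5 dva) and pooled
over neighbouring SF/orientation channels with Gaussian distance
weights, and the result R_LP enters the denominator of

    R_N = R_E^n / (sigma^n + R_LP^n).

Because the denominator builds up slowly, brief transients pass almost
unnormalised while sustained stimulation is compressed - the
transient/sustained dynamics characteristic of early visual cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from scipy import ndimage

from .exceptions import ConfigurationError, ParameterError

__all__ = [
    "NormalizationSpec",
    "NormalizedResponse",
    "energy",
    "lowpass_pool",
    "delayed_normalize",
    "run_model",
]


@dataclass(frozen=True)
class NormalizationSpec:
    """Parameters of the delayed-normalization stage.

    tau_n is in seconds; sigma_p_theta is in octaves and sigma_p_omega
    in degrees (orientation distance wrapped at 180 deg).
    """

    tau_n: float = 0.75  # temporal lowpass time constant, s
    gl_sd: float = 0.5  # spatial lowpass SD, dva
    sigma_semi: float = 0.07  # semisaturation constant
    exponent: float = 1.4
    pool_radius: int = 2  # +/- cells in the SF and orientation grids
    sigma_p_theta: float = 1.0  # octaves
    sigma_p_omega: float = 11.5  # degrees
    literal_printed_pool: bool = False  # keep the (corrupted) printed Eq-14 form

    def __post_init__(self):
        for name in ("tau_n", "gl_sd", "sigma_semi", "exponent",
                     "sigma_p_theta", "sigma_p_omega"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.pool_radius < 0:
            raise ParameterError("pool_radius must be >= 0")


def energy(rst: np.ndarray) -> np.ndarray:
    """Quadrature energy R_E = R_even^2 + R_odd^2; drops the phase axis.

    ``rst`` has shape (n_sf, n_ori, 2, T, H, W) with axis 2 = phase.
    """
    if rst.ndim < 3 or rst.shape[2] != 2:
        raise ParameterError("expected a phase axis of length 2 at position 2")
    return rst[:, :, 0] ** 2 + rst[:, :, 1] ** 2


def _pool_matrix(sf_set, ori_set, spec: NormalizationSpec) -> np.ndarray:
    """Row-normalised channel pooling weights, shape (S, O, S, O).

    Gaussian in (octave, degree) distance over a +/- pool_radius index
    neighbourhood; orientation wraps at 180 deg, the SF neighbourhood is
    truncated at the grid edges (weights renormalise automatically).
    """
    sf = np.asarray(sf_set, dtype=float)
    ori = np.asarray(ori_set, dtype=float)
    S, O = len(sf), len(ori)
    d_oct = np.log2(sf[:, None] / sf[None, :])
    d_ori = (ori[:, None] - ori[None, :] + 90.0) % 180.0 - 90.0
    if spec.literal_printed_pool:
        # the form as printed (kept for sensitivity analysis only); it is
        # not a Gaussian and is clipped at zero to stay a valid weight
        w = 1.0 - np.exp(-(np.abs(d_oct)[:, None, :, None]
                           / spec.sigma_p_theta ** 2
                           - np.abs(d_ori)[None, :, None, :]
                           / spec.sigma_p_omega ** 2))
        w = np.clip(w, 0.0, None) + 1e-12
    else:
        w = np.exp(-(d_oct[:, None, :, None] ** 2
                     / (2.0 * spec.sigma_p_theta ** 2)
                     + d_ori[None, :, None, :] ** 2
                     / (2.0 * spec.sigma_p_omega ** 2)))
    # restrict to the +/- pool_radius index neighbourhood
    r = spec.pool_radius
    idx = np.arange(S)
    in_sf = np.abs(idx[:, None] - idx[None, :]) <= r
    jdx = np.arange(O)
    d_j = np.abs(jdx[:, None] - jdx[None, :])
    in_or = np.minimum(d_j, O - d_j) <= r  # circular index distance
    w = w * in_sf[:, None, :, None] * in_or[None, :, None, :]
    w = w.reshape(S * O, S * O)
    w /= w.sum(axis=1, keepdims=True)
    return w.reshape(S, O, S, O)


def lowpass_pool(re: np.ndarray, spec: NormalizationSpec, rate: float,
                 pitch: float, sf_set, ori_set,
                 return_rl: bool = False):
    """Delayed normalization pool R_LP from the energy tensor.

    R_L = R_E filtered by the causal exponential H_L(t) = exp(-t/tau_n)
    (normalised to unit steady-state gain) and blurred by the unit-sum
    spatial Gaussian G_L; R_LP is the Gaussian-weighted average of R_L
    over the +/- pool_radius SF/orientation neighbourhood.
    """
    if re.shape[0] != len(sf_set) or re.shape[1] != len(ori_set):
        raise ConfigurationError("channel axes do not match the channel grids")
    a = re.dtype.type(np.exp(-1.0 / (spec.tau_n * rate)))
    # IIR realisation of the unit-sum discretised exponential kernel,
    # run as an explicit recursion over the (short) time axis
    rl = np.empty_like(re)
    rl[:, :, 0] = (1 - a) * re[:, :, 0]
    for k in range(1, re.shape[2]):
        rl[:, :, k] = (1 - a) * re[:, :, k] + a * rl[:, :, k - 1]
    sd_px = spec.gl_sd / pitch
    rl = ndimage.gaussian_filter1d(rl, sd_px, axis=-2, mode="constant",
                                   truncate=2.5)
    rl = ndimage.gaussian_filter1d(rl, sd_px, axis=-1, mode="constant",
                                   truncate=2.5, output=rl)

    S, O = len(sf_set), len(ori_set)
    w = _pool_matrix(sf_set, ori_set, spec).reshape(S * O, S * O)
    flat = rl.reshape(S * O, -1)
    rlp = (w.astype(re.dtype) @ flat).reshape(re.shape)
    if return_rl:
        return rlp, rl
    return rlp


def delayed_normalize(re: np.ndarray, rlp: np.ndarray,
                      spec: NormalizationSpec) -> np.ndarray:
    """Divisive normalization R_N = R_E^n / (sigma^n + R_LP^n)."""
    if np.any(re < 0) or np.any(rlp < 0):
        raise ParameterError("normalization requires non-negative energies")
    n = re.dtype.type(spec.exponent) if re.dtype.kind == "f" else spec.exponent
    num = np.power(re, n)
    den = np.power(rlp, n)
    den += re.dtype.type(spec.sigma_semi ** spec.exponent) \
        if re.dtype.kind == "f" else spec.sigma_semi ** spec.exponent
    num /= den
    return num


@dataclass
class NormalizedResponse:
    """Model output R_N over (theta, omega, t, y, x), with axis metadata."""

    rn: np.ndarray = field(repr=False)
    sf_set: np.ndarray
    ori_set: np.ndarray
    rate: float
    pitch: float
    extent: tuple
    spec: NormalizationSpec = None
    re: np.ndarray = field(default=None, repr=False)
    rlp: np.ndarray = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return self.rn.shape[2]

    def collapse_channels(self) -> np.ndarray:
        """Mean over SF and orientation channels -> (t, y, x)."""
        return self.rn.mean(axis=(0, 1))


def run_model(movie, bank, kernels, spec: NormalizationSpec = None,
              keep_intermediates: bool = False,
              precision: str = "single") -> NormalizedResponse:
    """Run the full five-stage model on a retinal movie.

    Stages: spatial log-Gabor filtering -> SF-matched temporal filtering
    -> quadrature energy -> spatiotemporal/channel lowpass pooling ->
    delayed divisive normalization.  Spatial convolution shares one
    padded frame FFT across all channels (both quadrature phases come
    from a single complex kernel); temporal convolution is a small
    Toeplitz product since only the first T kernel taps can influence a
    T-frame series.

    Parameters
    ----------
    movie : RetinalMovie
    bank : LogGaborBank
        Pitch must match the movie's.
    kernels : sequence of 1-D ndarray
        One discrete TRF kernel per bank SF, sampled at the movie rate
        (see :meth:`TRFFitResult.kernels_for`).
    spec : NormalizationSpec
    precision : {"single", "double"}
        Internal float width.  Single precision is the production
        default; double is available for numerical cross-checks.
    """
    import scipy.fft

    spec = spec or NormalizationSpec()
    if not np.isclose(movie.pitch, bank.pitch, rtol=1e-6):
        raise ConfigurationError("movie pitch does not match bank pitch")
    sf_set, ori_set = bank.sf_set, bank.ori_set
    if len(kernels) != len(sf_set):
        raise ConfigurationError("need one temporal kernel per SF channel")
    if precision not in ("single", "double"):
        raise ConfigurationError("precision must be 'single' or 'double'")
    fdt = np.float32 if precision == "single" else np.float64
    cdt = np.complex64 if precision == "single" else np.complex128

    frames = np.asarray(movie.frames, dtype=fdt)
    t, h, w = frames.shape
    kmax = max(k.extent_px for k in bank)
    sh = scipy.fft.next_fast_len(h + kmax - 1)
    sw = scipy.fft.next_fast_len(w + kmax - 1)
    F = scipy.fft.fft2(frames.astype(cdt), s=(sh, sw), axes=(-2, -1))

    re = np.empty((len(sf_set), len(ori_set), t, h, w), dtype=fdt)
    for i, theta in enumerate(sf_set):
        hk = np.asarray(kernels[i], dtype=fdt)[:t]
        # lower-triangular Toeplitz operator of the causal convolution
        L = np.zeros((t, t), dtype=cdt)
        for d in range(len(hk)):
            L[np.arange(d, t), np.arange(t - d)] = hk[d]
        for j, omega in enumerate(ori_set):
            kern = bank[(theta, omega)]
            K = scipy.fft.fft2(kern.weights.astype(cdt), s=(sh, sw))
            rs = scipy.fft.ifft2(F * K, axes=(-2, -1))
            o = (kern.extent_px - 1) // 2
            rs = rs[:, o:o + h, o:o + w]
            rst = (L @ rs.reshape(t, -1)).reshape(t, h, w)
            re[i, j] = np.abs(rst) ** 2  # |even + i*odd|^2 = even^2 + odd^2
    del F
    rlp = lowpass_pool(re, spec, movie.rate, movie.pitch, sf_set, ori_set,
                       return_rl=False)
    rn = delayed_normalize(re, rlp, spec)
    return NormalizedResponse(
        rn=rn, sf_set=sf_set, ori_set=ori_set,
        rate=movie.rate, pitch=movie.pitch, extent=movie.extent, spec=spec,
        re=re if keep_intermediates else None,
        rlp=rlp if keep_intermediates else None)
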