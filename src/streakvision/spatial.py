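"""Log-Gabor spatial filter bank with physiologically scaled bandwidths.

The bank covers seven spatial frequencies (0.25-4 cpd) and eight
orientations (22.5 deg spacing) in even/odd quadrature phase pairs.
Bandwidths are not constant: spatial-frequency bandwidth widens below a
critical SF of 2 cpd, and orientation bandwidth widens below 1 cpd as a
consequence of receptive-field (RF) size scaling with SF.  Filters are
constructed in the frequency domain as Gaussians in log radial frequency
and orientation, which guarantees a zero DC response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .exceptions import ConfigurationError, ParameterError

__all__ = [
    "BankSpec",
    "LogGaborKernel",
    "LogGaborBank",
    "sf_bandwidth",
    "fwhm_to_sigma",
    "rf_sigma",
    "orientation_bandwidth",
    "build_bank",
    "apply_spatial",
]

#: full width at half maximum of a unit-SD Gaussian
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

DEFAULT_SF_SET = (0.25, 0.4, 0.63, 1.0, 1.59, 2.52, 4.0)
DEFAULT_ORI_SET = (-67.5, -45.0, -22.5, 0.0, 22.5, 45.0, 67.5, 90.0)


@dataclass(frozen=True)
class BankSpec:
    """Parameters of the log-Gabor filter bank.

    Attributes
    ----------
    sf_set : tuple of float
        Channel spatial frequencies theta in cycles per degree (cpd).
    ori_set : tuple of float
        Channel orientations omega in degrees; the orientation of a
        filter is the orientation of its stripes, so a horizontal
        motion streak maximally drives the 0 deg channel.
    theta0 : float
        Critical SF (cpd) above which SF bandwidth is constant.
    w0 : float
        Asymptotic SF bandwidth (FWHM, octaves) at and above ``theta0``.
    beta0 : float
        RF width (2 sigma_RF, dva) at 1 cpd.
    """

    sf_set: tuple = DEFAULT_SF_SET
    ori_set: tuple = DEFAULT_ORI_SET
    theta0: float = 2.0
    w0: float = 1.5
    beta0: float = 1.0

    def __post_init__(self):
        sfs = np.asarray(self.sf_set, dtype=float)
        if sfs.ndim != 1 or np.any(np.diff(sfs) <= 0):
            raise ParameterError("sf_set must be strictly increasing")
        if np.any(sfs <= 0):
            raise ParameterError("spatial frequencies must be positive")


def sf_bandwidth(theta, theta0: float = 2.0, w0: float = 1.5):
    """Spatial-frequency bandwidth (FWHM, octaves) of the channel at ``theta``.

    Constant at ``w0`` for theta >= theta0; below the critical SF the
    bandwidth grows by 0.26 octaves per octave of SF decrease.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ParameterError("theta must be positive (cpd)")
    low = w0 - 0.26 * np.log2(theta / theta0)
    return np.where(theta >= theta0, w0, low)[()]


def fwhm_to_sigma(w):
    """Convert a Gaussian FWHM to a standard deviation (same units)."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ParameterError("FWHM must be non-negative")
    return (w / FWHM_PER_SIGMA)[()]


def rf_sigma(theta, beta0: float = 1.0):
    """Gaussian RF spatial constant sigma_RF (dva) for a channel at ``theta``.

    RF width (defined as 2 sigma_RF) follows 1/theta above 1 cpd and
    theta^-0.5 below 1 cpd, anchored at ``beta0`` dva width at 1 cpd.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ParameterError("theta must be positive (cpd)")
    hi = 0.5 * beta0 * theta ** -1.0
    lo = 0.5 * beta0 * theta ** -0.5
    return np.where(theta >= 1.0, hi, lo)[()]


def orientation_bandwidth(theta, beta0: float = 1.0):
    """Orientation bandwidth (FWHM, degrees) of a Gabor RF at SF ``theta``.

    Follows from the inherent trade-off between a Gabor's SF and the SD
    of its Gaussian aperture:  w_omega = 2 arctan(C b / theta) with
    C = sqrt(2 ln 2) and b = 1 / (2 pi sigma_RF(theta)).  Because
    sigma_RF * theta is constant (= beta0/2) at and above 1 cpd the
    bandwidth is constant there (~41 deg for beta0 = 1), and it grows
    towards low SFs (~100 deg at 0.1 cpd).
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ParameterError("theta must be positive (cpd)")
    c = np.sqrt(2.0 * np.log(2.0))
    b = 1.0 / (2.0 * np.pi * rf_sigma(theta, beta0))
    return np.degrees(2.0 * np.arctan(c * b / theta))[()]


@dataclass
class LogGaborKernel:
    """A single spatial kernel of the bank (one SF x orientation pair).

    ``weights`` is complex: the real part is the even-phase kernel, the
    imaginary part the odd-phase kernel (a quadrature pair).
    """

    theta: float
    omega: float
    sigma_theta: float  # log-frequency SD, octaves
    sigma_omega: float  # orientation SD, degrees
    pitch: float
    weights: np.ndarray = field(repr=False)

    @property
    def even(self) -> np.ndarray:
        return self.weights.real

    @property
    def odd(self) -> np.ndarray:
        return self.weights.imag

    @property
    def extent_px(self) -> int:
        return self.weights.shape[0]


def _odd(n: int) -> int:
    return int(n) | 1


def _make_kernel(theta, omega, sigma_theta_oct, sigma_omega_deg, size, pitch):
    """Construct one complex log-Gabor kernel in the frequency domain.

    The frequency-domain magnitude is a single-sided Gaussian in log
    radial frequency (SD in natural log = sigma_theta_oct * ln 2) and in
    orientation.  Single-sidedness (no mirror lobe at omega + 180 deg)
    makes the inverse transform a quadrature pair: real part even,
    imaginary part odd.
    """
    fx = scipy.fft.fftfreq(size, d=pitch)
    fy = scipy.fft.fftfreq(size, d=pitch)
    FX, FY = np.meshgrid(fx, fy, indexing="xy")
    f = np.hypot(FX, FY)
    # retinotopic y points up but image rows grow downward, so the
    # angular coordinate uses the negated row frequency; otherwise every
    # orientation channel would respond to its mirror image
    ang = np.arctan2(-FY, FX)

    sigma_ln = sigma_theta_oct * np.log(2.0)
    with np.errstate(divide="ignore"):
        radial = np.exp(-np.log(np.where(f > 0, f / theta, 1.0)) ** 2
                        / (2.0 * sigma_ln ** 2))
    radial[f == 0] = 0.0

    # the wave vector of a grating with stripes at omega points at omega+90
    lobe = np.radians(omega + 90.0)
    d = np.angle(np.exp(1j * (ang - lobe)))  # wrapped to (-pi, pi]
    sigma_om = np.radians(sigma_omega_deg)
    angular = np.exp(-d ** 2 / (2.0 * sigma_om ** 2))

    spectrum = radial * angular
    kernel = scipy.fft.fftshift(scipy.fft.ifft2(spectrum))
    # remove any residual DC leaked by discretisation
    kernel = kernel - kernel.mean()
    return kernel.astype(np.complex128)


class LogGaborBank:
    """The full 7 SF x 8 orientation quadrature bank at a given pitch."""

    def __init__(self, spec: BankSpec, pitch: float, kernels):
        self.spec = spec
        self.pitch = float(pitch)
        self.kernels = kernels  # dict[(theta, omega)] -> LogGaborKernel

    @property
    def sf_set(self):
        return np.asarray(self.spec.sf_set)

    @property
    def ori_set(self):
        return np.asarray(self.spec.ori_set)

    def __getitem__(self, key):
        return self.kernels[key]

    def __iter__(self):
        return iter(self.kernels.values())

    def __len__(self):
        return len(self.kernels)


def build_bank(spec: BankSpec = None, pitch: float = 3.36 / 51,
               max_canvas_px: int = None) -> LogGaborBank:
    """Build the log-Gabor bank at a given spatial sampling ``pitch``.

    Kernel side lengths scale with RF size: 8 sigma_RF(theta) evaluated
    with beta0 = 1 dva, rounded up to an odd pixel count.

    Parameters
    ----------
    spec : BankSpec
        Channel grid and bandwidth parameters.
    pitch : float
        Spatial sampling in dva per pixel; must resolve the highest SF
        with at least two samples per cycle.
    max_canvas_px : int, optional
        If given, raise if any kernel would exceed this side length.
    """
    spec = spec or BankSpec()
    nyquist = 1.0 / (2.0 * pitch)
    if max(spec.sf_set) > nyquist:
        raise ConfigurationError(
            f"pitch {pitch:.4f} dva/px cannot resolve {max(spec.sf_set)} cpd "
            f"(Nyquist {nyquist:.2f} cpd)")

    kernels = {}
    for theta in spec.sf_set:
        s_rf = float(rf_sigma(theta, beta0=1.0))
        size = _odd(int(np.ceil(8.0 * s_rf / pitch)))
        if max_canvas_px is not None and size > max_canvas_px:
            raise ConfigurationError(
                f"kernel for theta={theta} cpd needs {size} px, larger than "
                f"the canvas ({max_canvas_px} px)")
        s_theta = float(fwhm_to_sigma(sf_bandwidth(theta, spec.theta0, spec.w0)))
        s_omega = float(fwhm_to_sigma(orientation_bandwidth(theta, spec.beta0)))
        for omega in spec.ori_set:
            w = _make_kernel(theta, omega, s_theta, s_omega, size, pitch)
            kernels[(theta, omega)] = LogGaborKernel(
                theta=theta, omega=omega, sigma_theta=s_theta,
                sigma_omega=s_omega, pitch=pitch, weights=w)
    return LogGaborBank(spec, pitch, kernels)


def _same_slice(full: int, out: int, klen: int):
    start = (klen - 1) // 2
    return slice(start, start + out)


def convolve_frames(frames: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2-D convolve every frame with a (possibly complex) kernel.

    Zero-padded boundaries, 'same' output size.  FFTs are batched over
    the time axis, and a complex kernel yields both quadrature phases in
    one pass (real part = even response, imaginary part = odd).
    """
    t, h, w = frames.shape
    kh, kw = kernel.shape
    sh = scipy.fft.next_fast_len(h + kh - 1)
    sw = scipy.fft.next_fast_len(w + kw - 1)
    F = scipy.fft.fft2(frames, s=(sh, sw), axes=(-2, -1), workers=-1)
    K = scipy.fft.fft2(kernel, s=(sh, sw), workers=-1)
    out = scipy.fft.ifft2(F * K, axes=(-2, -1), workers=-1)
    return out[:, _same_slice(sh, h, kh), _same_slice(sw, w, kw)]


def apply_spatial(bank: LogGaborBank, movie) -> np.ndarray:
    """Convolve every movie frame with every kernel of the bank.

    Parameters
    ----------
    bank : LogGaborBank
    movie : RetinalMovie
        Its pitch must match the bank pitch.

    Returns
    -------
    ndarray, shape (n_sf, n_ori, 2, T, H, W), float32
        Spatial responses R_s; axis 2 is phase (0 even, 1 odd).
    """
    if not np.isclose(movie.pitch, bank.pitch, rtol=1e-6):
        raise ConfigurationError(
            f"movie pitch {movie.pitch} does not match bank pitch {bank.pitch}")
    frames = np.asarray(movie.frames, dtype=np.float64)
    n_sf, n_ori = len(bank.sf_set), len(bank.ori_set)
    t, h, w = frames.shape
    out = np.empty((n_sf, n_ori, 2, t, h, w), dtype=np.float32)
    for i, theta in enumerate(bank.sf_set):
        for j, omega in enumerate(bank.ori_set):
            k = bank[(theta, omega)]
            resp = convolve_frames(frames, k.weights)
            out[i, j, 0] = resp.real
            out[i, j, 1] = resp.imag
    return out
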