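"""Summaries of normalized-response tensors.

Spatial aggregates (where was activity?), channel engagement (which SF
and orientation channels carried it?), present-absent contrasts (what
did the motion streak itself contribute?) and the single-RF pass
demonstration of why fast motion is visible to parallel but not
orthogonal receptive fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .normalization import NormalizationSpec, NormalizedResponse, run_model
from .spatial import BankSpec, build_bank
from .stimulus import RetinalMovie

__all__ = [
    "aggregate_space",
    "channel_engagement",
    "condition_difference",
    "PeakChannel",
    "peak_channel",
    "principal_axis_angle",
    "rf_pass_demo",
]


def aggregate_space(rn) -> np.ndarray:
    """Sum R_N over channels and time -> a (y, x) activity map."""
    a = rn.rn if isinstance(rn, NormalizedResponse) else np.asarray(rn)
    return a.sum(axis=(0, 1, 2))


def channel_engagement(rn) -> np.ndarray:
    """Sum R_N over space and time -> a (theta, omega) engagement map."""
    a = rn.rn if isinstance(rn, NormalizedResponse) else np.asarray(rn)
    return a.sum(axis=(2, 3, 4))


def condition_difference(engagement_present: np.ndarray,
                         engagement_absent: np.ndarray) -> np.ndarray:
    """Elementwise present - absent engagement contrast."""
    p = np.asarray(engagement_present)
    a = np.asarray(engagement_absent)
    if p.shape != a.shape:
        raise ParameterError("engagement maps differ in shape")
    return p - a


def _axial_mean(angles_deg):
    """Circular mean and SD of axial data (period 180 deg)."""
    z = np.exp(2j * np.radians(np.asarray(angles_deg, dtype=float)))
    r = np.abs(z.mean())
    mean = np.degrees(np.angle(z.mean())) / 2.0
    # wrap into (-90, 90]
    mean = (mean + 90.0) % 180.0 - 90.0
    if mean == -90.0:
        mean = 90.0
    sd = np.degrees(np.sqrt(-2.0 * np.log(max(r, 1e-300)))) / 2.0
    return float(mean), float(sd)


@dataclass
class PeakChannel:
    """Peak of an engagement contrast and the trajectory it encodes."""

    peak_orientation: float  # circular mean retinal trajectory axis, deg
    peak_sf: float  # argmax SF of the contrast, cpd
    peak_contrast_orientation: float  # argmax orientation channel, deg
    dispersion: float  # +/- 2 circular SD of trajectory axes, deg


def peak_channel(contrast: np.ndarray, trajectory_angles_deg, sf_set,
                 ori_set) -> PeakChannel:
    """Locate the peak channel of a contrast and the mean trajectory axis.

    ``trajectory_angles_deg`` are per-trial retinal motion directions
    (math convention); they are folded onto the orientation axis
    (period 180 deg) before circular averaging.
    """
    contrast = np.asarray(contrast)
    if not np.any(contrast != 0):
        raise ParameterError("all-zero contrast: peak undefined")
    i, j = np.unravel_index(np.argmax(contrast), contrast.shape)
    mean, sd = _axial_mean(trajectory_angles_deg)
    return PeakChannel(peak_orientation=mean, peak_sf=float(sf_set[i]),
                       peak_contrast_orientation=float(ori_set[j]),
                       dispersion=2.0 * sd)


def principal_axis_angle(space_map: np.ndarray, threshold: float = 0.5):
    """Orientation (deg) of the principal axis of a thresholded map.

    Pixels above ``threshold`` x max enter a second-moment
    eigen-decomposition; the returned angle is the axis of largest
    variance in math convention (x rightward, y upward), in (-90, 90].
    Also returns the elongation (sqrt of the eigenvalue ratio).
    """
    m = np.asarray(space_map, dtype=float)
    mask = m >= threshold * m.max()
    ys, xs = np.nonzero(mask)
    w = m[mask]
    # image rows run top-down; flip to y upward
    y = -(ys - ys.mean())
    x = xs - xs.mean()
    cov = np.cov(np.stack([x, y]), aweights=w)
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, -1]
    ang = np.degrees(np.arctan2(vy, vx))
    ang = (ang + 90.0) % 180.0 - 90.0
    if ang == -90.0:
        ang = 90.0
    elong = float(np.sqrt(evals[-1] / max(evals[0], 1e-12)))
    return float(ang), elong


def rf_pass_demo(speed: float, rf_orientation: str, theta: float = 0.63,
                 kernels_for=None, rate: float = 480.0,
                 pitch: float = 2 * 3.36 / 51, travel: float = 6.0,
                 dot_sd: float = 0.1, tail_time: float = 0.3,
                 spec: NormalizationSpec = None):
    """Pass a small dot through a single log-Gabor RF and trace responses.

    The dot travels horizontally at constant ``speed`` (dva/s) through a
    RF centred on the canvas whose stripes are either parallel (0 deg)
    or orthogonal (90 deg) to the motion; the movie continues for
    ``tail_time`` after the pass so the lagged response plays out.  The
    default SF of 0.63 cpd puts the orthogonal polarity flicker at
    ~6 Hz for a 10 dva/s pass, in the temporal sweet spot of motion
    perception.  Returns the stagewise traces at the RF centre: spatial
    even/odd responses, temporally filtered responses, energy, delayed
    pool and normalized output.

    Parameters
    ----------
    kernels_for : callable
        ``kernels_for(sf_set, rate)`` returning discrete TRF kernels
        (e.g. :meth:`TRFFitResult.kernels_for`).
    """
    if speed <= 0:
        raise ParameterError("speed must be positive")
    if rf_orientation not in ("parallel", "orthogonal"):
        raise ParameterError("rf_orientation must be 'parallel' or 'orthogonal'")
    omega = 0.0 if rf_orientation == "parallel" else 90.0

    bank_spec = BankSpec(sf_set=(theta,), ori_set=(0.0, 90.0))
    bank = build_bank(bank_spec, pitch=pitch)
    kernels = kernels_for((theta,), rate)

    half = travel / 2.0
    n_pass = int(round(travel / speed * rate)) + 1
    n = n_pass + int(round(tail_time * rate))
    xs = np.linspace(-half, half, n_pass)
    margin = bank[(theta, omega)].extent_px // 2 + 2
    w = int(round(travel / pitch)) + 2 * margin
    h = 2 * margin + 1
    frames = np.zeros((n, h, w), dtype=np.float32)
    row = h // 2
    sd_px = dot_sd / pitch
    cols = (xs + half) / pitch + margin
    ax = np.arange(w)
    ay = np.arange(h)
    for i, c in enumerate(cols):
        g = np.exp(-((ax - c) ** 2)[None, :] / (2 * sd_px ** 2)
                   - ((ay - row) ** 2)[:, None] / (2 * sd_px ** 2))
        frames[i] = g
    extent = (-half - margin * pitch, half + margin * pitch,
              -(h // 2) * pitch, (h // 2) * pitch)
    movie = RetinalMovie(frames=frames, pitch=pitch, rate=rate,
                         extent=extent)

    from .spatial import convolve_frames
    import scipy.signal

    j = list(bank.ori_set).index(omega)
    rs = convolve_frames(movie.frames.astype(np.float64),
                         bank[(theta, omega)].weights)[:, row, w // 2]
    hk = np.asarray(kernels[0])
    rst = scipy.signal.fftconvolve(rs, hk, mode="full")[:n]

    resp = run_model(movie, bank, kernels, spec=spec or NormalizationSpec(),
                     keep_intermediates=True)
    t = np.arange(n) / rate
    return {
        "t": t,
        "spatial_even": rs.real, "spatial_odd": rs.imag,
        "filtered_even": rst.real, "filtered_odd": rst.imag,
        "energy": resp.re[0, j, :, row, w // 2],
        "pool": resp.rlp[0, j, :, row, w // 2],
        "rn": resp.rn[0, j, :, row, w // 2],
    }
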