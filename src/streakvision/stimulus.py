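"""Synthetic stimuli, saccades, target schedules and retinal movies.

This module emulates the study conditions of the intra-saccadic
motion-streak paradigm: a bandpass noise patch (cutoffs 0.33/1.02 cpd,
Gaussian aperture SD 0.56 dva, 100% Michelson contrast) is displaced
6.6 dva in 25 ms (36 frames at 1440 fps) strictly during a large
horizontal saccade (mean amplitude 17.6 dva, duration 53.6 ms), in five
direction conditions (static/inward/outward/upward/downward) crossed
with streak present/absent.  The renderer projects the screen geometry
into retinotopic coordinates (fovea origin, x rightward, y upward) by
subtracting gaze position from the target position frame by frame,
yielding the model input movie I(t, y, x).

Leftward-saccade trials are represented by mirroring, so all generated
trials use a rightward saccade; "outward" means in saccade direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from scipy import ndimage

from .exceptions import ParameterError, RenderError, SchedulingError

__all__ = [
    "StimulusPatch",
    "SaccadeTrajectory",
    "TargetTrajectory",
    "RetinalMovie",
    "SimulationScale",
    "FULL_SCALE",
    "TEST_SCALE",
    "COARSE_SCALE",
    "make_noise_patch",
    "synthesize_saccade",
    "schedule_target_motion",
    "render_retinal_movie",
    "retinal_rotation_label",
    "simulate_trial",
    "Trial",
]

DIRECTIONS = ("static", "inward", "outward", "upward", "downward")

#: unit displacement per condition, rightward saccade, x rightward, y upward
_DIRECTION_VECTORS = {
    "static": np.array([0.0, 0.0]),
    "outward": np.array([1.0, 0.0]),
    "inward": np.array([-1.0, 0.0]),
    "upward": np.array([0.0, 1.0]),
    "downward": np.array([0.0, -1.0]),
}


@dataclass
class StimulusPatch:
    """Bandpass noise patch in Michelson contrast units (mean grey = 0)."""

    pixels: np.ndarray = field(repr=False)
    pitch: float
    cutoff_lo: float
    cutoff_hi: float
    aperture_sd: float
    seed: int

    @property
    def size_px(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SaccadeTrajectory:
    """Gaze position samples (dva) around a single saccade."""

    gaze: np.ndarray = field(repr=False)  # (T, 2): x, y
    rate: float
    onset_idx: int
    offset_idx: int
    amplitude: float
    peak_velocity: float

    @property
    def n_samples(self) -> int:
        return self.gaze.shape[0]

    @property
    def duration(self) -> float:
        return (self.offset_idx - self.onset_idx) / self.rate


@dataclass
class TargetTrajectory:
    """Screen-coordinate target schedule (dva)."""

    position: np.ndarray = field(repr=False)  # (T, 2)
    visible: np.ndarray = field(repr=False)  # (T,) bool
    direction: str
    streak: str
    motion_onset_idx: int
    motion_offset_idx: int


@dataclass
class RetinalMovie:
    """Retinotopic contrast movie I(t, y, x).

    The origin (0, 0) dva is the fovea; x increases rightward, y upward.
    Row index 0 corresponds to the top of the canvas (largest y).
    """

    frames: np.ndarray = field(repr=False)  # (T, H, W)
    pitch: float
    rate: float
    extent: tuple  # (x_min, x_max, y_min, y_max) in dva

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def retinal_to_px(self, xy):
        """Map retinotopic (x, y) dva to fractional (row, col) indices."""
        x, y = xy
        col = (x - self.extent[0]) / self.pitch
        row = (self.extent[3] - y) / self.pitch
        return row, col


@dataclass(frozen=True)
class SimulationScale:
    """Spatial/temporal resolution of a simulation run.

    The full scale matches the experimental projection system (1440 Hz,
    51 px per 3.36 dva).  Coarser scales raise the pitch and lower the
    rate consistently; all physical parameters stay in dva / seconds.
    The pitch of any scale must keep the highest bank SF (4 cpd) below
    Nyquist, which caps the pitch at 0.125 dva/px.  The default canvas
    spans the full retinal excursion of the target over all direction
    conditions (inward trials reach about -8.5 dva) plus the patch
    footprint and amplitude jitter.
    """

    pitch: float = 3.36 / 51
    rate: float = 1440.0
    extent: tuple = (-10.5, 20.5, -9.0, 9.0)


FULL_SCALE = SimulationScale()
#: CI resolution: ~1.8x coarser pitch (still resolving 4 cpd), 480 Hz
TEST_SCALE = SimulationScale(pitch=0.118, rate=480.0)
#: battery resolution for many-trial simulations: coarsest admissible
#: pitch, 240 Hz (the 25 ms motion still spans 6 frames)
COARSE_SCALE = SimulationScale(pitch=0.124, rate=240.0)


def _odd(n: int) -> int:
    return int(n) | 1


def make_noise_patch(seed: int = 7, cutoff_lo: float = 0.33,
                     cutoff_hi: float = 1.02, aperture_sd: float = 0.56,
                     size_px: int = 51, pitch: float = 3.36 / 51,
                     amplitude: float = 1.0) -> StimulusPatch:
    """Generate the bandpass-filtered noise patch used as saccade target.

    White Gaussian noise is filtered in the frequency domain with a
    log-Gaussian annulus whose amplitude falls to 1/sqrt(2) (-3 dB in
    power) at ``cutoff_lo`` and ``cutoff_hi``.  The result is normalised
    to peak |contrast| ``amplitude`` (100% Michelson by default) before
    the Gaussian aperture is applied multiplicatively.
    """
    if size_px % 2 == 0:
        raise ParameterError("size_px must be odd")
    nyq = 1.0 / (2.0 * pitch)
    if not (0.0 < cutoff_lo < cutoff_hi < nyq):
        raise ParameterError(
            f"need 0 < cutoff_lo < cutoff_hi < Nyquist ({nyq:.2f} cpd)")

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((size_px, size_px))
    if amplitude == 0.0:
        return StimulusPatch(np.zeros((size_px, size_px)), pitch,
                             cutoff_lo, cutoff_hi, aperture_sd, seed)

    f = np.hypot(*np.meshgrid(scipy.fft.fftfreq(size_px, d=pitch),
                              scipy.fft.fftfreq(size_px, d=pitch)))
    fc = np.sqrt(cutoff_lo * cutoff_hi)
    # amplitude = 2^-1/2 at the cutoffs -> -3 dB points of the power spectrum
    s = np.log(cutoff_hi / fc) / np.sqrt(np.log(2.0))
    with np.errstate(divide="ignore"):
        filt = np.exp(-np.log(np.where(f > 0, f / fc, 1.0)) ** 2 / (2 * s ** 2))
    filt[f == 0] = 0.0

    patch = scipy.fft.ifft2(scipy.fft.fft2(noise) * filt).real
    patch *= amplitude / np.max(np.abs(patch))

    half = (size_px - 1) / 2.0
    ax = (np.arange(size_px) - half) * pitch
    r2 = ax[None, :] ** 2 + ax[:, None] ** 2
    patch *= np.exp(-r2 / (2.0 * aperture_sd ** 2))
    return StimulusPatch(patch, pitch, cutoff_lo, cutoff_hi, aperture_sd, seed)


def synthesize_saccade(amplitude: float = 17.6, direction: str = "right",
                       duration: float = 0.0536, vertical_bias: float = 0.0,
                       rate: float = 1440.0, start=(0.0, 0.0),
                       pre_time: float = 0.02, post_time: float = 0.1,
                       total_time: float = None) -> SaccadeTrajectory:
    """Synthesize a smooth saccadic gaze trajectory.

    A minimum-jerk position profile is used: the velocity is unimodal
    and symmetric with peak velocity 1.875 * amplitude / duration (for a
    17.6 dva, 53.6 ms saccade: ~616 dva/s, within the empirically
    observed range).  ``vertical_bias`` adds a linear vertical component
    over the course of the saccade (a small upward bias is typical of
    horizontal saccades).
    """
    if amplitude < 0:
        raise ParameterError("amplitude must be >= 0")
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    if direction not in ("left", "right"):
        raise ParameterError("direction must be 'left' or 'right'")

    n_pre = int(round(pre_time * rate))
    n_sacc = int(round(duration * rate))
    if total_time is None:
        n = n_pre + n_sacc + int(round(post_time * rate)) + 1
    else:
        # fixed series length regardless of the (jittered) duration, so
        # trials of one battery can be compared sample by sample
        n = int(round(total_time * rate)) + 1
        if n < n_pre + n_sacc + 2:
            raise ParameterError("total_time too short for the saccade")
    t = np.arange(n) / rate
    onset = n_pre
    offset = n_pre + n_sacc

    u = np.clip((t - t[onset]) / (n_sacc / rate), 0.0, 1.0)
    profile = 10 * u ** 3 - 15 * u ** 4 + 6 * u ** 5  # minimum jerk, 0 -> 1
    sign = 1.0 if direction == "right" else -1.0
    gaze = np.empty((n, 2))
    gaze[:, 0] = start[0] + sign * amplitude * profile
    gaze[:, 1] = start[1] + vertical_bias * profile

    v = np.linalg.norm(np.gradient(gaze, 1.0 / rate, axis=0), axis=1)
    peak_v = float(v.max()) if amplitude > 0 else 0.0
    return SaccadeTrajectory(gaze=gaze, rate=rate, onset_idx=onset,
                             offset_idx=offset, amplitude=amplitude,
                             peak_velocity=peak_v)


def schedule_target_motion(direction: str, streak: str,
                           saccade: SaccadeTrajectory,
                           start_position=(18.25, 0.0),
                           distance: float = 6.6,
                           motion_duration: float = 0.025,
                           start_latency: float = 0.010) -> TargetTrajectory:
    """Build the target's screen trajectory for one trial.

    The displacement spans exactly ``round(motion_duration * rate)``
    frames at constant velocity (streak present) or is blanked for the
    motion interval with the target reappearing at the endpoint (streak
    absent).  The motion window must lie strictly inside the saccade.
    """
    if direction not in DIRECTIONS:
        raise ParameterError(f"unknown direction {direction!r}")
    if streak not in ("present", "absent"):
        raise ParameterError("streak must be 'present' or 'absent'")

    rate = saccade.rate
    n = saccade.n_samples
    n_motion = int(round(motion_duration * rate))
    onset = saccade.onset_idx + int(round(start_latency * rate))
    offset = onset + n_motion - 1

    if direction != "static" and offset >= saccade.offset_idx:
        raise SchedulingError(
            f"motion window [{onset}, {offset}] does not end before saccade "
            f"offset (sample {saccade.offset_idx}); reduce start_latency or "
            f"motion_duration")

    start = np.asarray(start_position, dtype=float)
    disp = distance * _DIRECTION_VECTORS[direction]
    position = np.tile(start, (n, 1))
    visible = np.ones(n, dtype=bool)

    if direction != "static":
        frac = np.arange(n_motion) / (n_motion - 1)
        position[onset:offset + 1] = start + frac[:, None] * disp
        position[offset + 1:] = start + disp
        if streak == "absent":
            # blank during the motion interval; reappear at the endpoint
            visible[onset:offset] = False
            position[onset:offset + 1] = start + disp
    return TargetTrajectory(position=position, visible=visible,
                            direction=direction, streak=streak,
                            motion_onset_idx=onset, motion_offset_idx=offset)


def render_retinal_movie(patch: StimulusPatch, saccade: SaccadeTrajectory,
                         target: TargetTrajectory,
                         extent=(-10.5, 20.5, -9.0, 9.0),
                         dtype=np.float32,
                         subframes: int = 1) -> RetinalMovie:
    """Render the retinotopic input movie I(t, y, x).

    Per frame the patch is inserted centered at the retinal position
    target - gaze, with sub-pixel placement by bilinear interpolation.
    Invisible frames render the uniform background (contrast 0).

    ``subframes`` emulates a display running faster than the model
    sampling rate: each movie frame is the average of ``subframes``
    placements at linearly interpolated retinal positions within the
    frame interval.  At coarse model rates this preserves the motion
    blur (the oriented intra-frame smear) that a 1440 fps projection
    produces on the retina; without it, fast motion degenerates into a
    train of widely spaced flashes.
    """
    pitch = patch.pitch
    x_min, x_max, y_min, y_max = extent
    w = int(round((x_max - x_min) / pitch)) + 1
    h = int(round((y_max - y_min) / pitch)) + 1
    n = saccade.n_samples
    if target.position.shape[0] != n:
        raise RenderError("saccade and target trajectories differ in length")
    if subframes < 1:
        raise ParameterError("subframes must be >= 1")

    frames = np.zeros((n, h, w), dtype=dtype)
    k = patch.size_px
    half = (k - 1) // 2
    retinal = target.position - saccade.gaze
    weight = np.float64(1.0 / subframes)
    # a screen step larger than this is a displacement (blank jump), not
    # motion, and must not be smeared by subframe interpolation
    max_motion_step = 2.0  # dva per model frame

    for i in range(n):
        if not target.visible[i]:
            continue
        for j in range(subframes):
            if i + 1 < n and subframes > 1:
                f = j / subframes
                gaze = (1.0 - f) * saccade.gaze[i] + f * saccade.gaze[i + 1]
                step = np.linalg.norm(target.position[i + 1]
                                      - target.position[i])
                if step <= max_motion_step and target.visible[i + 1]:
                    tpos = (1.0 - f) * target.position[i] \
                        + f * target.position[i + 1]
                else:
                    tpos = target.position[i]
                x, y = tpos - gaze
            else:
                x, y = retinal[i]
            row = (y_max - y) / pitch
            col = (x - x_min) / pitch
            r0 = int(np.floor(row))
            c0 = int(np.floor(col))
            fr, fc = row - r0, col - c0
            # bilinear sub-pixel shift of the patch, integer placement
            shifted = ndimage.shift(patch.pixels, (fr, fc), order=1,
                                    mode="constant", cval=0.0,
                                    prefilter=False)
            top, left = r0 - half, c0 - half
            if top < 0 or left < 0 or top + k > h or left + k > w:
                raise RenderError(
                    f"target footprint leaves the canvas at frame {i} "
                    f"(retinal position x={x:.2f}, y={y:.2f} dva)")
            frames[i, top:top + k, left:left + k] += \
                (weight * shifted).astype(dtype)
    return RetinalMovie(frames=frames, pitch=pitch, rate=saccade.rate,
                        extent=tuple(extent))


def retinal_rotation_label(saccade_direction: str, target_direction: str) -> str:
    """Classify the rotation of the retinal trajectory as CW or CCW.

    The label is the sign of the cross product between the
    saccade-induced retinal velocity (opposite to gaze velocity) and the
    combined retinal velocity (target motion minus gaze).  Only vertical
    target motion defines a rotation; other directions are 'undefined'.
    """
    if target_direction not in ("upward", "downward"):
        return "undefined"
    if saccade_direction not in ("left", "right"):
        raise ParameterError("saccade_direction must be 'left' or 'right'")
    g = np.array([1.0, 0.0]) if saccade_direction == "right" else np.array([-1.0, 0.0])
    v_sacc = -g  # retinal slip of the static scene
    v_target = _DIRECTION_VECTORS[target_direction]
    v_comb = v_target - g
    cross = v_sacc[0] * v_comb[1] - v_sacc[1] * v_comb[0]
    return "cw" if cross < 0 else "ccw"


@dataclass
class Trial:
    """One synthetic trial: movie plus its generating trajectories."""

    movie: RetinalMovie
    saccade: SaccadeTrajectory
    target: TargetTrajectory
    patch: StimulusPatch
    direction: str
    streak: str
    seed: int

    @property
    def retinal_trajectory(self) -> np.ndarray:
        return self.target.position - self.saccade.gaze

    def retinal_motion_angle(self) -> float:
        """Direction (deg, math convention) of the target's retinal
        displacement over the motion window."""
        r = self.retinal_trajectory
        d = r[self.target.motion_offset_idx] - r[self.target.motion_onset_idx]
        return float(np.degrees(np.arctan2(d[1], d[0])))

    def min_retinal_speed(self) -> float:
        """Minimum retinal speed (dva/s) of the target over the motion
        window.  Outward motion partially stabilises the target on the
        retina mid-saccade, so this is far lower than for a static
        target swept by the same saccade."""
        r = self.retinal_trajectory
        v = np.gradient(r, 1.0 / self.movie.rate, axis=0)
        sl = slice(self.target.motion_onset_idx,
                   self.target.motion_offset_idx + 1)
        return float(np.linalg.norm(v[sl], axis=1).min())


def simulate_trial(direction: str, streak: str, seed: int,
                   scale: SimulationScale = FULL_SCALE,
                   amplitude_mean: float = 17.6, amplitude_sd: float = 1.0,
                   duration_mean: float = 0.0536, duration_sd: float = 0.0033,
                   vertical_bias_mean: float = 0.15,
                   vertical_bias_sd: float = 0.10,
                   eccentricity: float = 18.25,
                   motion_latency_mean: float = 0.010,
                   motion_latency_sd: float = 0.0015,
                   distance: float = 6.6, motion_duration: float = 0.025,
                   patch_seed: int = 7, pre_time: float = 0.02,
                   post_time: float = 0.08,
                   duration_budget: float = 0.070) -> Trial:
    """Generate one fully seeded synthetic trial.

    Saccade amplitude, duration, vertical bias and the intra-saccadic
    motion-onset latency are drawn from Gaussians around the study's
    summary statistics (the same noise patch is reused across trials,
    mirroring the experiment).  All randomness derives from ``seed``.
    """
    rng = np.random.default_rng(seed)
    amp = float(np.clip(rng.normal(amplitude_mean, amplitude_sd),
                        amplitude_mean - 2.5 * amplitude_sd,
                        amplitude_mean + 2.5 * amplitude_sd))
    dur = float(np.clip(rng.normal(duration_mean, duration_sd), 0.040,
                        duration_budget))
    vbias = float(rng.normal(vertical_bias_mean, vertical_bias_sd))
    lat_hi = dur - motion_duration - 3.0 / scale.rate
    lat = float(np.clip(rng.normal(motion_latency_mean, motion_latency_sd),
                        0.002, max(0.002, lat_hi)))

    size_px = _odd(int(round(3.36 / scale.pitch)))
    patch = make_noise_patch(seed=patch_seed, size_px=size_px,
                             pitch=scale.pitch)
    # fixed series length across trials: the post-saccadic window absorbs
    # the duration jitter (durations are clipped at duration_budget)
    saccade = synthesize_saccade(amplitude=amp, direction="right",
                                 duration=dur, vertical_bias=vbias,
                                 rate=scale.rate, pre_time=pre_time,
                                 total_time=pre_time + duration_budget
                                 + post_time)
    target = schedule_target_motion(direction, streak, saccade,
                                    start_position=(eccentricity, 0.0),
                                    distance=distance,
                                    motion_duration=motion_duration,
                                    start_latency=lat)
    # emulate the 1440 fps projection at coarser model rates
    subframes = max(1, int(round(1440.0 / scale.rate)))
    movie = render_retinal_movie(patch, saccade, target, extent=scale.extent,
                                 subframes=subframes)
    return Trial(movie=movie, saccade=saccade, target=target, patch=patch,
                 direction=direction, streak=streak, seed=seed)
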