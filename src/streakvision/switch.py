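"""The predictive switch model for intra-saccadic gaze correction.

The model holds a learned sensorimotor contingency xbar - the average
channel-collapsed response a saccade over a static scene produces - and
compares, sample by sample, the predicted positive visual change
(spatially pooled maxima of the differentiated contingency within a
+/- w_i temporal window) with the measured positive change of the
current trial.  The prediction error y_k = dz+_k - dxbar+_k triggers a
"switch" from internal prediction to external measurement when it
crosses a threshold lambda derived from the contingency's own
variability.  The first switch time is the moment the system notices
that the target moved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .normalization import NormalizationSpec, run_model
from .spatial import BankSpec, build_bank
from .stimulus import SimulationScale, TEST_SCALE, simulate_trial

__all__ = [
    "Contingency",
    "SwitchTrace",
    "build_contingency",
    "robust_threshold",
    "predicted_change",
    "measured_change",
    "run_switch",
    "pos_sum_diff",
    "run_battery",
]


@dataclass
class Contingency:
    """Learned saccade-induced response pattern and switch threshold."""

    xbar: np.ndarray = field(repr=False)  # (T, H, W)
    lam: float
    wi: int  # integration half-window, samples
    rate: float
    saccade_window: tuple  # (onset_idx, offset_idx) used for the baseline

    @property
    def n_samples(self) -> int:
        return self.xbar.shape[0]


def _pos_diff_series(x: np.ndarray) -> np.ndarray:
    """Spatial max of the positive part of the temporal difference.

    Series index k holds max_yx( max(x[k] - x[k-1], 0) ); k = 0 is 0.
    """
    d = np.diff(x, axis=0)
    s = np.maximum(d, 0.0).max(axis=(1, 2))
    return np.concatenate([[0.0], s])


def robust_threshold(series: np.ndarray, window: tuple, c: float = 3.0) -> float:
    """Median + c * 1.4826 * MAD of a positive-change series in a window."""
    lo, hi = window
    s = np.asarray(series[lo:hi + 1], dtype=float)
    med = np.median(s)
    mad = np.median(np.abs(s - med))
    return float(med + c * 1.4826 * mad)


def build_contingency(static_rn_trials, wi: int, rate: float,
                      saccade_window: tuple, c: float = 3.0) -> Contingency:
    """Average static-condition responses into a contingency.

    Parameters
    ----------
    static_rn_trials : sequence of ndarray, each (T, H, W)
        Channel-collapsed R_N of static-condition trials.
    wi : int
        Integration half-window in samples (15 ms at the model rate).
    saccade_window : (int, int)
        Sample range of the saccade, over which the threshold baseline
        is computed.
    c : float
        Multiplier of the robust (MAD-based) deviation in the threshold.
    """
    trials = list(static_rn_trials)
    if not trials:
        raise ParameterError("need at least one static trial")
    shape = trials[0].shape
    if any(t.shape != shape for t in trials):
        raise ParameterError("static trials differ in shape")
    xbar = np.mean(np.stack(trials), axis=0)
    lam = robust_threshold(_pos_diff_series(xbar), saccade_window, c)
    return Contingency(xbar=xbar, lam=lam, wi=int(wi), rate=rate,
                       saccade_window=tuple(saccade_window))


def predicted_change(contingency: Contingency, k: int = None) -> np.ndarray:
    """Predicted positive change dxbar+_k, windowed over [k-wi, k+wi].

    Returns the full series when ``k`` is None, else the scalar at k.
    The window is clipped at the series ends.
    """
    base = _pos_diff_series(contingency.xbar)
    wi = contingency.wi
    if wi > 0:
        n = base.shape[0]
        out = np.empty(n)
        for i in range(n):
            out[i] = base[max(0, i - wi):min(n, i + wi + 1)].max()
    else:
        out = base
    return out if k is None else float(out[k])


def predicted_change_map(contingency: Contingency) -> np.ndarray:
    """Location-resolved prediction: the positive temporal difference of
    xbar, maximum-filtered over the +/- wi window at every location.

    During a saccade the retinal image moves, so the temporal window
    grants the prediction spatial tolerance along the sweep path as
    well ("greater temporal uncertainty, and thereby also greater
    spatial range").  Shape (T, H, W).
    """
    d = np.diff(contingency.xbar, axis=0)
    d = np.concatenate([np.zeros_like(d[:1]), np.maximum(d, 0.0)])
    if contingency.wi > 0:
        from scipy import ndimage
        d = ndimage.maximum_filter1d(d, size=2 * contingency.wi + 1,
                                     axis=0, mode="nearest")
    return d


def _measured_change_map(trial_collapsed: np.ndarray) -> np.ndarray:
    d = np.diff(np.asarray(trial_collapsed), axis=0)
    return np.concatenate([np.zeros_like(d[:1]), np.maximum(d, 0.0)])


def measured_change(trial_collapsed: np.ndarray, k: int = None):
    """Measured positive change dz+_k (instantaneous, single sample)."""
    s = _pos_diff_series(np.asarray(trial_collapsed))
    return s if k is None else float(s[k])


@dataclass
class SwitchTrace:
    """Per-trial switch-model time series."""

    pred_change: np.ndarray = field(repr=False)
    meas_change: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)  # prediction error
    K: np.ndarray = field(repr=False)  # 0/1 switch indicator
    x_est: np.ndarray = field(repr=False)  # accumulated position estimate
    lam: float
    rate: float
    switch_idx: int | None

    @property
    def switch_time(self) -> float | None:
        """First switch time in seconds (series origin), or None."""
        if self.switch_idx is None:
            return None
        return self.switch_idx / self.rate

    @property
    def switch_idx_interp(self) -> float | None:
        """First threshold crossing with subsample (linear) precision.

        The integer switch index quantises crossing times to the model
        sampling step; interpolating the crossing of y through lambda
        between the last sub- and the first supra-threshold sample
        recovers timing differences finer than one sample.
        """
        k = self.switch_idx
        if k is None:
            return None
        if k == 0 or self.y[k] == self.y[k - 1]:
            return float(k)
        frac = (self.lam - self.y[k - 1]) / (self.y[k] - self.y[k - 1])
        return k - 1 + float(np.clip(frac, 0.0, 1.0))


def run_switch(trial_collapsed: np.ndarray,
               contingency: Contingency,
               comparison: str = "local",
               measurement_window: bool = False) -> SwitchTrace:
    """Run the switch model on one trial's collapsed response.

    y_k = dz+_k - dxbar+_k; K_k = 1 iff y_k > lambda; the position
    estimate integrates x_{k+1} = x_k + dxbar+_k + K_k * y_k.

    With ``comparison="local"`` (default) the measured change of every
    retinotopic location is compared against the windowed prediction at
    that same location, and y_k pools the largest local prediction
    error over space; activity appearing where the saccade alone never
    produces any is then inherently surprising.  ``comparison="global"``
    compares the two spatially pooled scalar series instead (location-
    blind).  With ``measurement_window`` the measured change uses the
    same +/- w_i window as the prediction (symmetric variant).
    """
    trial_collapsed = np.asarray(trial_collapsed)
    if trial_collapsed.shape != contingency.xbar.shape:
        raise ParameterError("trial and contingency shapes do not match")
    if comparison not in ("local", "global"):
        raise ParameterError("comparison must be 'local' or 'global'")
    pred = predicted_change(contingency)
    if measurement_window:
        tmp = Contingency(xbar=trial_collapsed, lam=contingency.lam,
                          wi=contingency.wi, rate=contingency.rate,
                          saccade_window=contingency.saccade_window)
        meas = predicted_change(tmp)
    else:
        meas = measured_change(trial_collapsed)
    if comparison == "local":
        pred_map = predicted_change_map(contingency)
        if measurement_window:
            tmp = Contingency(xbar=trial_collapsed, lam=contingency.lam,
                              wi=contingency.wi, rate=contingency.rate,
                              saccade_window=contingency.saccade_window)
            meas_map = predicted_change_map(tmp)
        else:
            meas_map = _measured_change_map(trial_collapsed)
        y = np.max(meas_map - pred_map, axis=(1, 2))
    else:
        y = meas - pred
    K = (y > contingency.lam).astype(int)
    x_est = np.concatenate([[0.0], np.cumsum(pred + K * y)])[:-1]
    hits = np.nonzero(K)[0]
    idx = int(hits[0]) if hits.size else None
    return SwitchTrace(pred_change=pred, meas_change=meas, y=y, K=K,
                       x_est=x_est, lam=contingency.lam,
                       rate=contingency.rate, switch_idx=idx)


def pos_sum_diff(y_present: np.ndarray, y_absent: np.ndarray,
                 time_resolved: bool = False):
    """Positive sum of differences between two prediction-error series."""
    p = np.asarray(y_present, dtype=float)
    a = np.asarray(y_absent, dtype=float)
    if p.shape != a.shape:
        raise ParameterError("series are not aligned")
    d = np.maximum(p - a, 0.0)
    return d if time_resolved else float(d.sum())


def run_battery(n_per_cell: int = 10, directions=None, streaks=None,
                seed: int = 0, scale: SimulationScale = TEST_SCALE,
                bank=None, kernels=None, spec: NormalizationSpec = None,
                wi_ms: float = 15.0, c: float = 3.0,
                n_static: int = None, store: dict = None,
                trial_kwargs: dict = None) -> pd.DataFrame:
    """Simulate a battery of trials and tabulate switch times.

    A contingency is first built from ``n_static`` dedicated static
    trials (default: ``n_per_cell``); each condition trial is then run
    through the early-vision model and the switch model.  Everything is
    seeded: trial seeds are drawn from one generator derived from
    ``seed``, so the battery is bit-reproducible.

    Parameters
    ----------
    store : dict, optional
        If given, filled with light per-trial artifacts under the key
        ``(direction, streak, i)``: channel engagement (theta x omega),
        the retinal motion angle (deg), the prediction-error series and
        trial timing indices.  The contingency is stored under
        ``"contingency"``.
    trial_kwargs : dict, optional
        Extra keyword arguments for :func:`simulate_trial` (e.g.
        shorter ``pre_time``/``post_time`` windows at coarse scales).

    Returns
    -------
    DataFrame with one row per trial: condition, streak, seed, switch
    index, switch time relative to saccade onset and to motion onset
    (ms), the saccade offset, and lambda.
    """
    from .summaries import channel_engagement

    directions = list(directions or
                      ("static", "inward", "outward", "upward", "downward"))
    streaks = list(streaks or ("present", "absent"))
    if bank is None:
        bank = build_bank(BankSpec(), pitch=scale.pitch)
    if kernels is None:
        raise ParameterError(
            "kernels is required: pass TRFFitResult.kernels_for(sf_set, rate)"
            " output for the battery scale")
    spec = spec or NormalizationSpec()
    wi = int(round(wi_ms / 1000.0 * scale.rate))
    n_static = n_per_cell if n_static is None else n_static
    trial_kwargs = trial_kwargs or {}

    rng = np.random.default_rng(seed)

    def one_trial(direction, streak, trial_seed):
        trial = simulate_trial(direction, streak, trial_seed, scale=scale,
                               **trial_kwargs)
        resp = run_model(trial.movie, bank, kernels, spec=spec)
        return trial, resp.collapse_channels(), channel_engagement(resp)

    # contingency from dedicated static trials
    static, engagements, sacc_windows = [], [], []
    for i in range(n_static):
        trial, x, eng = one_trial("static", "present",
                                  int(rng.integers(2 ** 31)))
        static.append(x)
        engagements.append(eng)
        sacc_windows.append((trial.saccade.onset_idx,
                             trial.saccade.offset_idx))
    window = (int(np.mean([w[0] for w in sacc_windows])),
              int(np.mean([w[1] for w in sacc_windows])))
    contingency = build_contingency(static, wi=wi, rate=scale.rate,
                                    saccade_window=window, c=c)
    if store is not None:
        store["contingency"] = contingency
        for i, eng in enumerate(engagements):
            store[("static_reference", "present", i)] = {"engagement": eng}

    rows = []
    for direction in directions:
        # streak present/absent pairs are yoked: same saccade, same
        # timing, only the motion interval differs, so the present -
        # absent contrast isolates the streak itself
        pair_seeds = [int(rng.integers(2 ** 31)) for _ in range(n_per_cell)]
        for streak in streaks:
            for i in range(n_per_cell):
                trial_seed = pair_seeds[i]
                trial, x, eng = one_trial(direction, streak, trial_seed)
                tr = run_switch(x, contingency)
                onset = trial.saccade.onset_idx
                motion_on = trial.target.motion_onset_idx
                idx = tr.switch_idx
                ki = tr.switch_idx_interp
                rows.append({
                    "direction": direction, "streak": streak,
                    "seed": trial_seed, "switch_idx": idx,
                    "lambda": contingency.lam,
                    "switch_ms_from_saccade_onset":
                        np.nan if idx is None
                        else (idx - onset) / scale.rate * 1e3,
                    "switch_ms_interp_from_saccade_onset":
                        np.nan if ki is None
                        else (ki - onset) / scale.rate * 1e3,
                    "switch_ms_from_motion_onset":
                        np.nan if idx is None
                        else (idx - motion_on) / scale.rate * 1e3,
                    "saccade_offset_ms_from_onset":
                        (trial.saccade.offset_idx - onset) / scale.rate * 1e3,
                })
                if store is not None:
                    store[(direction, streak, i)] = {
                        "engagement": eng,
                        "angle": trial.retinal_motion_angle(),
                        "y": tr.y,
                        "pred": tr.pred_change,
                        "meas": tr.meas_change,
                        "switch_idx": idx,
                        "saccade_onset": onset,
                        "saccade_offset": trial.saccade.offset_idx,
                        "motion_onset": motion_on,
                        "motion_offset": trial.target.motion_offset_idx,
                        "min_retinal_speed": trial.min_retinal_speed(),
                    }
    return pd.DataFrame(rows)
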