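"""ROI selection by evoked fields, hemispheric mirroring, and lateralization indices.

The lateralization index (LI) of band-limited power is

    LI = (Left - Right) / (Left + Right)

where *Left* is power averaged over the left-hemisphere sensors of interest
and *Right* the corresponding value for the mirrored right-hemisphere
sensors.  Positive LI indicates left-hemispheric dominance, i.e. relatively
stronger power over the stimulated hemisphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import EpochSet, SensorLayout
from .spectral import SegmentSpectrum, TimeFreqResult

logger = logging.getLogger(__name__)


class RoiError(RuntimeError):
    """Raised when no channel meets the evoked-field criterion."""


@dataclass
class LateralizationProfile:
    """Frequency-resolved LI with optional baseline and normalized values."""

    freqs: np.ndarray
    li: np.ndarray
    left_power: np.ndarray
    right_power: np.ndarray
    roi_left: list
    roi_right: list
    baseline_li: Optional[np.ndarray] = None

    @property
    def normalized_li(self) -> Optional[np.ndarray]:
        if self.baseline_li is None:
            return None
        return self.li - self.baseline_li


def select_roi(
    offset_epochs: EpochSet,
    layout: SensorLayout,
    z_thresh: float = 4.0,
    stim_frequency: Optional[float] = None,
    peak_window: tuple = (0.005, 0.030),
    pre_window: tuple = (-0.010, 0.0),
) -> list:
    """Left-hemisphere channels with a clear pulse-locked evoked field.

    An algorithmic criterion standing in for visual sensor selection: the
    trial-averaged data are re-averaged across the stimulation pulses of the
    pre-offset ON period, and a channel is selected when the peak absolute
    deflection within ``peak_window`` after a pulse exceeds ``z_thresh``
    times the pre-pulse noise SD.  Deterministic given its input.
    """
    if stim_frequency is None:
        if not isinstance(offset_epochs.condition, (int, float)):
            raise ValueError("stimulation frequency required for pulse-locked averaging")
        stim_frequency = float(offset_epochs.condition)
    fs = offset_epochs.sample_rate
    if offset_epochs.n_trials < 3:
        raise ValueError("need at least 3 trials for evoked statistics")

    # pulse times within the epoch: the last pulse sits at t = 0, earlier
    # ones at -k/f; keep pulses comfortably inside the epoch
    k = np.arange(1, int(stim_frequency * 3.2))
    pulse_t = -k / stim_frequency
    pulse_t = pulse_t[pulse_t > offset_epochs.times[0] + 0.1]
    if pulse_t.size < 3:
        raise ValueError("too few pre-offset pulses for evoked averaging")
    i_pre = int(round(pre_window[0] * fs))
    i_post = int(round((peak_window[1] + 0.004) * fs))
    lags = np.arange(i_pre, i_post + 1)
    centers = np.round((pulse_t - offset_epochs.times[0]) * fs).astype(int)
    # per-trial pulse-triggered average: trials x channels x lag
    pta = offset_epochs.data[:, :, centers[:, None] + lags[None, :]].mean(axis=2)
    lag_s = lags / fs

    pre = (lag_s >= pre_window[0]) & (lag_s < pre_window[1])
    post = (lag_s >= peak_window[0]) & (lag_s < peak_window[1])
    grand = pta.mean(axis=0)  # channels x lag
    base_mean = grand[:, pre].mean(axis=1)
    # channel-wise peak lag from the grand average, then an across-trials
    # t-statistic of the per-trial response at that lag (robust to
    # autocorrelated background activity)
    post_idx = np.nonzero(post)[0]
    peak_lag = post_idx[np.abs(grand[:, post] - base_mean[:, None]).argmax(axis=1)]
    resp = (pta[:, np.arange(pta.shape[1]), peak_lag]
            - pta[:, :, pre].mean(axis=2))  # trials x channels
    n_tr = resp.shape[0]
    sd = resp.std(axis=0, ddof=1)
    sd = np.maximum(sd, 1e-12)
    z = np.abs(resp.mean(axis=0)) / (sd / np.sqrt(n_tr))

    selected = [
        cid
        for i, (cid, h) in enumerate(zip(layout.channel_ids, layout.hemisphere))
        if h == "left" and z[i] > z_thresh
    ]
    if not selected:
        raise RoiError(
            f"no left-hemisphere channel exceeded z = {z_thresh}; reduce the threshold"
        )
    return selected


def lateralization_index(left_power, right_power):
    """(Left - Right) / (Left + Right); NaN (flagged) where the sum is zero.

    Accepts scalars or arrays of non-negative band-limited power aggregates.
    """
    L = np.asarray(left_power, dtype=float)
    R = np.asarray(right_power, dtype=float)
    if (L < 0).any() or (R < 0).any():
        raise ValueError("power aggregates must be non-negative")
    total = L + R
    zero = total == 0
    if zero.any():
        logger.warning("LI undefined for %d bin(s) with zero total power", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        li = np.where(zero, np.nan, (L - R) / np.where(zero, 1.0, total))
    return li if li.ndim else float(li)


def _roi_indices(layout: SensorLayout, roi_left: list) -> tuple:
    if not roi_left:
        raise ValueError("empty left ROI")
    if layout.mirror_map is None:
        raise ValueError("layout has no mirror map; call build_mirror_map first")
    left_idx = [layout.index(c) for c in roi_left]
    right_idx = [layout.index(layout.mirror_map[c]) for c in roi_left]
    return left_idx, right_idx


def aftereffect_li(
    spectrum: SegmentSpectrum,
    layout: SensorLayout,
    roi_left: list,
) -> LateralizationProfile:
    """Per-frequency LI of the post-train segment spectrum over the mirrored ROI."""
    left_idx, right_idx = _roi_indices(layout, roi_left)
    left = spectrum.power[left_idx].mean(axis=0)
    right = spectrum.power[right_idx].mean(axis=0)
    return LateralizationProfile(
        freqs=spectrum.freqs,
        li=np.asarray(lateralization_index(left, right)),
        left_power=left,
        right_power=right,
        roi_left=list(roi_left),
        roi_right=[layout.mirror_map[c] for c in roi_left],
    )


def normalized_li(
    stim_profile: LateralizationProfile,
    baseline_profile: LateralizationProfile,
) -> LateralizationProfile:
    """After-effect LI minus baseline LI on an identical frequency grid."""
    if (stim_profile.freqs.shape != baseline_profile.freqs.shape
            or not np.allclose(stim_profile.freqs, baseline_profile.freqs, atol=1e-6)):
        raise ValueError("frequency grids of the two profiles do not match")
    return LateralizationProfile(
        freqs=stim_profile.freqs,
        li=stim_profile.li,
        left_power=stim_profile.left_power,
        right_power=stim_profile.right_power,
        roi_left=stim_profile.roi_left,
        roi_right=stim_profile.roi_right,
        baseline_li=baseline_profile.li,
    )


def state_masks(
    times: np.ndarray,
    schedule,
    on_margin: float = 0.5,
    off_margin: float = 0.155,
    green_windows: Optional[np.ndarray] = None,
) -> dict:
    """Boolean sample masks for stimulation ON and OFF (pause) states.

    ON excludes the first ``on_margin`` s of each train (filter transients);
    OFF excludes the first ``off_margin`` s of each pause (wavelet leakage).
    Optionally intersected with green-cue windows of the tapping task.
    """
    on = np.zeros(times.size, dtype=bool)
    off = np.zeros(times.size, dtype=bool)
    for onset, offset in schedule.on_intervals():
        on |= (times >= onset + on_margin) & (times < offset)
    for start, stop in schedule.off_intervals(duration=times[-1]):
        off |= (times >= start + off_margin) & (times < stop)
    if green_windows is not None:
        green = np.zeros(times.size, dtype=bool)
        for lo, hi in green_windows:
            green |= (times >= lo) & (times < hi)
        on &= green
        off &= green
    return {"on": on, "off": off}


def tapping_li(
    tfr: TimeFreqResult,
    layout: SensorLayout,
    roi_left: list,
    masks: dict,
    band: tuple = (14.0, 18.0),
) -> dict:
    """Band-limited LI per stimulation state during the tapping task.

    ``tfr`` is the time-frequency transform of the continuous tapping
    recording (single trial); ``masks`` maps state names to boolean sample
    masks (see :func:`state_masks`).  Returns ``{state: li}``.
    """
    left_idx, right_idx = _roi_indices(layout, roi_left)
    bp = tfr.band_power(*band)  # channels x times
    if bp.ndim == 3:
        bp = bp.mean(axis=0)
    valid = tfr.valid if tfr.valid is not None else np.ones(tfr.times.size, bool)
    out = {}
    for state, mask in masks.items():
        m = mask & valid
        if not m.any():
            out[state] = np.nan
            continue
        left = bp[left_idx][:, m].mean()
        right = bp[right_idx][:, m].mean()
        out[state] = lateralization_index(left, right)
    return out


def cohort_tapping_li(
    li_by_condition: dict,
    exclude_condition: Optional[float] = 16.0,
) -> dict:
    """Drop the condition whose stimulation artifact falls inside the analysis band.

    ``li_by_condition`` maps stimulation frequency to ``{state: li}``; the
    excluded condition (default 16 Hz, inside the 14-18 Hz band) is removed
    with a log entry.
    """
    out = {}
    for cond, lis in li_by_condition.items():
        if exclude_condition is not None and np.isclose(float(cond), exclude_condition):
            logger.info("excluding %s Hz condition: artifact inside the analysis band", cond)
            continue
        out[cond] = lis
    return out


def aftereffect_persistence(
    tfr,
    layout: SensorLayout,
    roi_left: list,
    band: tuple = (10.0, 23.0),
    pause_window: tuple = (1.0, 2.845),
    n_sd: float = 2.0,
    method: str = "crossing",
) -> float:
    """How long post-train ROI band power stays above the pause-level noise.

    Returns the first post-offset time at which trial-averaged ROI band power
    drops below ``pause mean + n_sd * pause SD``.  The reference statistics
    are computed over the *late* part of the stimulation pause (default from
    1 s after the offset), where any after-effect has fully decayed, so the
    noise floor is not inflated by the effect under measurement.  NaN when
    power never exceeds the threshold.

    ``tfr`` may be a single :class:`TimeFreqResult` or a list of them
    (e.g. one per subject), in which case the group-average time course is
    analyzed.  ``method="crossing"`` returns the first sub-threshold sample;
    ``method="fit"`` fits an exponential ``a * exp(-t/tau)`` to the
    post-offset excess power and returns its analytic threshold crossing,
    which is less sensitive to noise wiggles near the crossing point.
    """
    tfrs = tfr if isinstance(tfr, (list, tuple)) else [tfr]
    left_idx, _ = _roi_indices(layout, roi_left)
    curves = []
    for one in tfrs:
        bp = one.band_power(*band)
        if bp.ndim == 3:
            bp = bp.mean(axis=0)
        curves.append(bp[left_idx].mean(axis=0))
    ref = tfrs[0]
    series = np.mean(curves, axis=0)
    pause = ref.time_mask(*pause_window)
    if not pause.any():
        raise ValueError("pause window outside epoch")
    floor = series[pause].mean()
    noise_sd = series[pause].std(ddof=1)
    thresh = floor + n_sd * noise_sd
    valid = ref.valid if ref.valid is not None else np.ones(ref.times.size, bool)
    post = (ref.times >= 0) & valid
    t_post = ref.times[post]
    x = series[post]
    if x.size == 0 or x[0] <= thresh:
        return float("nan")
    if method == "fit":
        from scipy.optimize import curve_fit

        fit_mask = t_post <= pause_window[0]
        excess = np.maximum(x[fit_mask] - floor, 1e-12 * max(floor, 1e-300))
        try:
            (a, tau_hat), _ = curve_fit(
                lambda t, a, tau: a * np.exp(-t / tau),
                t_post[fit_mask], excess,
                p0=(float(excess[0]), 0.2), maxfev=5000,
            )
        except RuntimeError:
            return float("nan")
        if a <= n_sd * noise_sd:
            return float("nan")
        return float(tau_hat * np.log(a / (n_sd * noise_sd)))
    below = np.nonzero(x < thresh)[0]
    return float(t_post[below[0]]) if below.size else float(t_post[-1])
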