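"""Train-offset detection, epoch extraction, and amplitude-based artifact rejection."""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np

from .core import EpochSet, RawRecording

logger = logging.getLogger(__name__)


class RejectionError(RuntimeError):
    """Raised when artifact rejection would discard most of the data."""


def detect_train_offsets(
    raw: RawRecording,
    method: str = "events",
    artifact_channel: Optional[str] = None,
    mad_factor: float = 8.0,
    min_gap: float = 1.0,
) -> np.ndarray:
    """Times of the last stimulation pulse of each DBS train.

    With ``method="events"`` the train_offset rows of the event table are
    authoritative.  With ``method="artifact_channel"`` pulses are detected on
    the named artifact-dominated channel as samples exceeding
    ``mad_factor x median absolute deviation``; consecutive supra-threshold
    samples separated by more than ``min_gap`` seconds start a new train, and
    the last pulse of each group is returned.  Returns an empty array for a
    stimulation-free recording.
    """
    if method == "events":
        return raw.events.onsets("train_offset")
    if method != "artifact_channel":
        raise ValueError(f"unknown method {method!r}")
    if artifact_channel is None:
        raise ValueError("artifact_channel method requires a channel name")
    x = raw.data[raw.layout.index(artifact_channel)]
    mad = np.median(np.abs(x - np.median(x)))
    thresh = mad_factor * mad
    supra = np.nonzero(np.abs(x) > thresh)[0]
    if supra.size == 0:
        return np.array([])
    gaps = np.diff(supra) > min_gap * raw.sample_rate
    group_ends = np.append(supra[:-1][gaps], supra[-1])
    return group_ends / raw.sample_rate


def make_offset_epochs(
    raw: RawRecording,
    offsets: np.ndarray,
    half_width: float = 3.5,
    condition=None,
) -> EpochSet:
    """Epochs of ``+-half_width`` s centered on each train offset (t = 0).

    Offsets closer than ``half_width`` to either edge of the recording are
    dropped with a log entry.
    """
    offsets = np.asarray(offsets, dtype=float)
    fs = raw.sample_rate
    n_half = int(round(half_width * fs))
    centers = np.round(offsets * fs).astype(int)
    ok = (centers - n_half >= 0) & (centers + n_half < raw.n_samples)
    if (~ok).any():
        logger.info("dropping %d edge train(s) closer than %.2f s to a record edge",
                    int((~ok).sum()), half_width)
    centers = centers[ok]
    data = np.stack([raw.data[:, c - n_half:c + n_half + 1] for c in centers]) \
        if centers.size else np.empty((0, raw.layout.n_channels, 2 * n_half + 1))
    times = np.arange(-n_half, n_half + 1) / fs
    if condition is None:
        condition = raw.schedule.stim_frequency if raw.schedule is not None else "baseline"
    return EpochSet(data=data, times=times, sample_rate=fs, alignment="train_offset",
                    condition=condition, kept_trial_ids=np.nonzero(ok)[0],
                    layout=raw.layout)


def make_consecutive_epochs(raw: RawRecording, length: float = 7.0) -> EpochSet:
    """Non-overlapping back-to-back epochs of the stated length; remainder discarded.

    Used for the DBS-OFF baseline, where no train offsets exist to align to.
    """
    fs = raw.sample_rate
    n_len = int(round(length * fs))
    n_epochs = raw.n_samples // n_len
    if n_epochs == 0:
        warnings.warn(f"recording shorter than {length} s yields no epochs")
        data = np.empty((0, raw.layout.n_channels, n_len))
    else:
        data = raw.data[:, :n_epochs * n_len].reshape(
            raw.layout.n_channels, n_epochs, n_len).transpose(1, 0, 2)
    times = np.arange(n_len) / fs
    return EpochSet(data=data, times=times, sample_rate=fs, alignment="consecutive",
                    condition="baseline", layout=raw.layout)


def reject_artifacts(epochs: EpochSet, z_threshold: float = 6.0) -> EpochSet:
    """Drop trials with outlying peak amplitude.

    Per channel, the peak absolute amplitude of each trial is z-scored across
    trials using robust statistics (median and scaled MAD, so that a single
    extreme trial cannot mask itself); a trial is rejected when its maximum z
    over channels exceeds the threshold.  An automated stand-in for visual
    inspection of muscle and movement artifacts.
    """
    if epochs.n_trials < 5:
        raise ValueError("need at least 5 trials to estimate rejection statistics")
    peaks = np.abs(epochs.data).max(axis=2)  # trials x channels
    med = np.median(peaks, axis=0)
    mad = 1.4826 * np.median(np.abs(peaks - med), axis=0)
    mad[mad == 0] = np.inf
    z = ((peaks - med) / mad).max(axis=1)
    keep = z <= z_threshold
    n_drop = int((~keep).sum())
    if n_drop > 0.5 * epochs.n_trials:
        raise RejectionError(
            f"{n_drop}/{epochs.n_trials} trials rejected; review the z threshold"
        )
    if n_drop:
        logger.info("rejected %d trial(s) at z > %.1f", n_drop, z_threshold)
    return EpochSet(
        data=epochs.data[keep],
        times=epochs.times,
        sample_rate=epochs.sample_rate,
        alignment=epochs.alignment,
        condition=epochs.condition,
        kept_trial_ids=np.asarray(epochs.kept_trial_ids)[keep],
        layout=epochs.layout,
    )
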