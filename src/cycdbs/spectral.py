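"""Morlet time-frequency power / intertrial coherence and short-segment after-effect spectra.

Wavelet convention
------------------
"Wavelet length" is the fixed total temporal support ``L`` (in seconds) of
the wavelet at *every* analysis frequency, with a Gaussian envelope of
``sigma_t = L / 6`` (support ~ +-3 sigma).  A fixed duration, rather than a
fixed number of cycles, bounds the temporal leakage of stimulation-period
activity into the post-stimulation analysis windows: with ``L = 0.3`` s no
ON-period energy can leak beyond ``L/2 = 0.15`` s after the final pulse,
which is why the after-effect statistics start at 0.155 s.  A frequency-
dependent constant-cycles mode is available via ``n_cycles``.

Wavelets are complex exponentials under the Gaussian envelope, corrected to
zero mean and normalized to unit continuous energy
(``integral |psi|^2 dt = 1``); convolution is scaled by ``1/fs`` so that
coefficients approximate the continuous wavelet transform independently of
the sample rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .core import EpochSet


@dataclass
class TimeFreqResult:
    """Time-frequency decomposition over channels x frequencies x times.

    ``power`` is trial-averaged (or per-trial when ``per_trial`` outputs were
    requested), in amplitude^2 units; ``itc`` lies in [0, 1] and is only
    defined for >= 2 trials.  ``valid`` flags time samples farther than half
    a wavelet length from the epoch edges; values outside are edge-
    contaminated and excluded from statistics.
    """

    power: np.ndarray  # (channels, freqs, times) or (trials, channels, freqs, times)
    freqs: np.ndarray
    times: np.ndarray
    wavelet_length: float
    itc: Optional[np.ndarray] = None  # (channels, freqs, times)
    n_trials: int = 0
    valid: Optional[np.ndarray] = None  # (times,) bool
    baseline_window: Optional[tuple] = None
    condition: object = None

    def band_power(self, fmin: float, fmax: float) -> np.ndarray:
        """Mean power over freqs in [fmin, fmax]; shape (..., channels, times)."""
        sel = (self.freqs >= fmin - 1e-9) & (self.freqs <= fmax + 1e-9)
        return self.power[..., sel, :].mean(axis=-2)

    def time_mask(self, start: float, stop: float) -> np.ndarray:
        m = (self.times >= start - 1e-12) & (self.times < stop - 1e-12)
        if self.valid is not None:
            m &= self.valid
        return m

    def save_h5(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("power", data=self.power.astype(np.float32))
            if self.itc is not None:
                f.create_dataset("itc", data=self.itc.astype(np.float32))
            f.create_dataset("freqs", data=self.freqs)
            f.create_dataset("times", data=self.times)
            if self.valid is not None:
                f.create_dataset("valid", data=self.valid)
            f.attrs["wavelet_length"] = self.wavelet_length
            f.attrs["n_trials"] = self.n_trials


def morlet_wavelet(freq: float, sample_rate: float, length: float) -> np.ndarray:
    """Complex Morlet wavelet of fixed temporal support ``length`` (sigma_t = length/6).

    Zero-mean corrected and normalized to unit continuous energy.
    """
    n_half = int(round(length / 2 * sample_rate))
    t = np.arange(-n_half, n_half + 1) / sample_rate
    sigma = length / 6.0
    g = np.exp(-(t**2) / (2 * sigma**2))
    carrier = np.exp(2j * np.pi * freq * t)
    # subtract the Gaussian-weighted carrier mean so the wavelet has zero mean
    kappa = np.sum(g * carrier) / np.sum(g)
    psi = g * (carrier - kappa)
    energy = np.sum(np.abs(psi) ** 2) / sample_rate
    return psi / np.sqrt(energy)


def _convolve_same(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """FFT-based 'same' convolution of `kernel` along the last axis of `data`."""
    n = data.shape[-1]
    m = kernel.size
    nfft = int(2 ** np.ceil(np.log2(n + m - 1)))
    D = np.fft.fft(data, n=nfft, axis=-1)
    K = np.fft.fft(kernel, n=nfft)
    out = np.fft.ifft(D * K, axis=-1)
    start = (m - 1) // 2
    return out[..., start:start + n]


def morlet_tfr(
    epochs: EpochSet,
    freqs: Optional[np.ndarray] = None,
    wavelet_length: float = 0.5,
    n_cycles: Optional[float] = None,
    output: str = "average",
    decim: int = 1,
) -> TimeFreqResult:
    """Morlet wavelet transform of an epoch set.

    Parameters
    ----------
    freqs : array, default 5..60 Hz in 1 Hz steps
    wavelet_length : float
        Fixed temporal support in seconds (ignored when ``n_cycles`` given).
    n_cycles : float, optional
        Constant-cycles mode: per-frequency support ``n_cycles / freq``.
    output : {"average", "complex"}
        "average" returns trial-mean power and ITC.  "complex" returns a
        ``(TimeFreqResult, coefficients)`` tuple where ``coefficients`` holds
        the per-trial complex wavelet coefficients
        (trials x channels x freqs x times) and ``power`` the per-trial
        magnitudes squared.
    decim : int
        Temporal decimation factor applied to the output.
    """
    if freqs is None:
        freqs = np.arange(5.0, 61.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    fs = epochs.sample_rate
    nyq = fs / 2.0
    if np.any(freqs >= nyq) or np.any(freqs <= 0):
        raise ValueError(f"frequencies must lie in (0, {nyq}) Hz")
    epoch_len = epochs.times[-1] - epochs.times[0]
    max_len = wavelet_length if n_cycles is None else float(n_cycles / freqs.min())
    if max_len >= epoch_len:
        raise ValueError("wavelet longer than epoch")
    data = epochs.data
    n_trials, n_ch, n_t = data.shape
    out_times = epochs.times[::decim]
    n_out = out_times.size

    avg_power = np.zeros((n_ch, len(freqs), n_out))
    plv_sum = np.zeros((n_ch, len(freqs), n_out), dtype=complex)
    per_trial = (np.zeros((n_trials, n_ch, len(freqs), n_out), dtype=complex)
                 if output == "complex" else None)

    for fi, f in enumerate(freqs):
        L = wavelet_length if n_cycles is None else n_cycles / f
        psi = morlet_wavelet(f, fs, L)
        w = _convolve_same(data, np.conj(psi[::-1])) / fs
        w = w[..., ::decim]
        avg_power[:, fi] = (np.abs(w) ** 2).mean(axis=0)
        mag = np.abs(w)
        mag[mag == 0] = np.inf
        plv_sum[:, fi] = (w / mag).sum(axis=0)
        if per_trial is not None:
            per_trial[:, :, fi] = w

    # edge samples within half the (longest) wavelet of the epoch borders
    half = (max_len if n_cycles is not None else wavelet_length) / 2.0
    valid = (out_times >= epochs.times[0] + half) & (out_times <= epochs.times[-1] - half)

    itc_map = np.abs(plv_sum) / n_trials if n_trials >= 2 else None
    if output == "complex":
        return TimeFreqResult(power=np.abs(per_trial) ** 2, freqs=freqs, times=out_times,
                              wavelet_length=wavelet_length, itc=itc_map,
                              n_trials=n_trials, valid=valid,
                              condition=epochs.condition), per_trial
    return TimeFreqResult(power=avg_power, freqs=freqs, times=out_times,
                          wavelet_length=wavelet_length, itc=itc_map,
                          n_trials=n_trials, valid=valid, condition=epochs.condition)


def itc(per_trial_coefficients: np.ndarray) -> np.ndarray:
    """Intertrial coherence: resultant length of unit phase vectors across trials.

    ``ITC = | mean_trials W / |W| |`` per (channel, frequency, time) bin;
    zero-magnitude coefficients are excluded from the mean.
    """
    w = np.asarray(per_trial_coefficients)
    if w.shape[0] < 2:
        raise ValueError("ITC requires at least 2 trials")
    mag = np.abs(w)
    nonzero = mag > 0
    unit = np.where(nonzero, w / np.where(nonzero, mag, 1.0), 0.0)
    counts = nonzero.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.abs(unit.sum(axis=0)) / counts
    return np.where(counts > 0, out, np.nan)


def baseline_correct(tfr: TimeFreqResult, baseline_window: tuple) -> TimeFreqResult:
    """Subtract the frequency-specific mean power over the baseline window.

    The baseline value is computed per channel and frequency; ITC is left
    untouched.  Edge-invalid samples are excluded from the baseline mean.
    """
    mask = tfr.time_mask(*baseline_window)
    if not mask.any():
        raise ValueError(f"baseline window {baseline_window} outside epoch times")
    base = tfr.power[..., mask].mean(axis=-1, keepdims=True)
    return TimeFreqResult(
        power=tfr.power - base,
        freqs=tfr.freqs,
        times=tfr.times,
        wavelet_length=tfr.wavelet_length,
        itc=tfr.itc,
        n_trials=tfr.n_trials,
        valid=tfr.valid,
        baseline_window=tuple(baseline_window),
        condition=tfr.condition,
    )


@dataclass
class SegmentSpectrum:
    """Trial-averaged power spectrum of the 155 ms post-train segment.

    The frequency grid is the natural DFT grid of the window,
    ``k / 0.155 s = k * 6.45 Hz`` for ``k = 1..9`` (6.45-58.06 Hz), which is
    what limits the after-effect analysis to that resolution.
    """

    power: np.ndarray  # (channels, n_bins)
    freqs: np.ndarray  # Hz
    window: tuple
    n_trials: int
    per_trial: Optional[np.ndarray] = None  # (trials, channels, n_bins)


def segment_spectrum(
    epochs: EpochSet,
    window: tuple = (0.005, 0.160),
    k_max: int = 9,
    keep_trials: bool = False,
) -> SegmentSpectrum:
    """Hann-tapered periodogram of the post-offset segment on the 6.45 Hz grid.

    Per trial and channel, the demeaned, Hann-tapered segment of
    ``window`` (155 ms by default) is Fourier transformed; power at bins
    ``k / T_window`` for ``k = 1..k_max`` is averaged over trials.
    """
    t0, t1 = window
    if t0 < epochs.times[0] - 1e-12 or t1 > epochs.times[-1] + 1.0 / epochs.sample_rate + 1e-12:
        raise ValueError(f"window {window} extends past epoch times")
    idx = epochs.time_indices(t0, t1)
    n = idx.size
    if n < 2 * k_max:
        raise ValueError("window too short for the requested number of bins")
    seg = epochs.data[:, :, idx]
    freqs_grid, pxx = sps.periodogram(
        seg, fs=epochs.sample_rate, window="hann", detrend="constant", axis=-1
    )
    sel = slice(1, k_max + 1)
    per_trial = pxx[:, :, sel]
    return SegmentSpectrum(
        power=per_trial.mean(axis=0) if per_trial.shape[0] else per_trial.sum(axis=0),
        freqs=freqs_grid[sel],
        window=(t0, t1),
        n_trials=epochs.n_trials,
        per_trial=per_trial if keep_trials else None,
    )
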