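"""Morlet transform, ITC, baseline correction, and segment spectra."""

import numpy as np
import pytest

from cycdbs.core import EpochSet
from cycdbs.spectral import (
    baseline_correct,
    itc,
    morlet_tfr,
    morlet_wavelet,
    segment_spectrum,
    _convolve_same,
)

from conftest import FS, sinusoid_epochs


class TestMorlet:
    def test_sinusoid_peaks_at_its_frequency_everywhere(self):
        ep = sinusoid_epochs(freq=20.0)
        tfr = morlet_tfr(ep, freqs=np.arange(5.0, 61.0), wavelet_length=0.5)
        interior = tfr.valid
        argmax = tfr.freqs[tfr.power[0][:, interior].argmax(axis=0)]
        assert (argmax == 20.0).all()

    def test_matches_analytic_wavelet_response(self):
        # a unit-energy Morlet responds to cos(2 pi f t) with
        # |W|^2 = sqrt(pi) * sigma / 2 at the carrier frequency
        ep = sinusoid_epochs(freq=20.0)
        tfr = morlet_tfr(ep, freqs=np.array([20.0]), wavelet_length=0.5)
        mid = np.argmin(np.abs(tfr.times))
        sigma = 0.5 / 6.0
        analytic = np.sqrt(np.pi) * sigma / 2.0
        assert tfr.power[0, 0, mid] == pytest.approx(analytic, rel=0.01)

    def test_amplitude_doubling_quadruples_power(self):
        a = morlet_tfr(sinusoid_epochs(amp=1.0), freqs=np.array([20.0]),
                       wavelet_length=0.5)
        b = morlet_tfr(sinusoid_epochs(amp=2.0), freqs=np.array([20.0]),
                       wavelet_length=0.5)
        assert np.allclose(b.power, 4 * a.power)

    def test_dc_signal_rejected_by_zero_mean_wavelet(self):
        ref = morlet_tfr(sinusoid_epochs(freq=20.0), freqs=np.arange(5.0, 61.0),
                         wavelet_length=0.5)
        t = np.arange(0, 4, 1 / FS)
        dc = EpochSet(data=np.ones((1, 1, t.size)), times=t - 2, sample_rate=FS,
                      alignment="consecutive")
        tfr = morlet_tfr(dc, freqs=np.arange(5.0, 61.0), wavelet_length=0.5)
        mid = np.argmin(np.abs(tfr.times))
        assert tfr.power[0, :, mid].max() < 1e-6 * ref.power[0, :, mid].max()

    def test_agrees_with_direct_convolution(self):
        # two-implementation oracle: FFT convolution vs direct np.convolve
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 3, 400))
        psi = morlet_wavelet(15.0, FS, 0.3)
        fast = _convolve_same(x, np.conj(psi[::-1]))
        direct = np.empty_like(fast)
        for i in range(2):
            for j in range(3):
                direct[i, j] = np.convolve(x[i, j], np.conj(psi[::-1]), mode="same")
        assert np.max(np.abs(fast - direct)) < 1e-6 * np.max(np.abs(direct))

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            morlet_tfr(sinusoid_epochs(), freqs=np.array([120.0]), wavelet_length=0.3)

    def test_wavelet_longer_than_epoch_rejected(self):
        with pytest.raises(ValueError):
            morlet_tfr(sinusoid_epochs(duration=0.4), freqs=np.array([20.0]),
                       wavelet_length=0.5)

    def test_trial_order_invariance(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(6, 2, 400))
        t = np.arange(400) / FS
        ep = EpochSet(data=data, times=t, sample_rate=FS, alignment="consecutive")
        ep_rev = EpochSet(data=data[::-1], times=t, sample_rate=FS,
                          alignment="consecutive")
        a = morlet_tfr(ep, freqs=np.array([10.0, 20.0]), wavelet_length=0.3)
        b = morlet_tfr(ep_rev, freqs=np.array([10.0, 20.0]), wavelet_length=0.3)
        assert np.allclose(a.power, b.power)
        assert np.allclose(a.itc, b.itc)

    def test_on_period_leakage_bounded_by_wavelet_support(self):
        """With oscillatory power only at t<0, power at t >= 0.155 s is <1%
        of the ON level for 300 ms wavelets (the after-effect window rationale)."""
        t = np.arange(0, 7, 1 / FS) - 3.5
        x = np.where(t < 0, np.cos(2 * np.pi * 20 * t), 0.0)
        ep = EpochSet(data=x[None, None, :], times=t, sample_rate=FS,
                      alignment="train_offset")
        tfr = morlet_tfr(ep, freqs=np.array([20.0]), wavelet_length=0.3)
        on_level = tfr.power[0, 0, tfr.time_mask(-2.0, -0.5)].mean()
        post = tfr.power[0, 0, tfr.time_mask(0.155, 1.0)].max()
        assert post < 0.01 * on_level


class TestItc:
    def test_identical_trials_give_unity(self):
        ep = sinusoid_epochs(n_trials=10)
        _, coeff = morlet_tfr(ep, freqs=np.array([20.0]), wavelet_length=0.5,
                              output="complex")
        mid = np.argmin(np.abs(ep.times))
        assert itc(coeff)[0, 0, mid] == pytest.approx(1.0, abs=1e-9)

    def test_antiphase_trials_cancel(self):
        ep = sinusoid_epochs(n_trials=2, phases=[0.0, np.pi])
        _, coeff = morlet_tfr(ep, freqs=np.array([20.0]), wavelet_length=0.5,
                              output="complex")
        mid = np.argmin(np.abs(ep.times))
        assert itc(coeff)[0, 0, mid] == pytest.approx(0.0, abs=1e-6)

    def test_random_phases_match_resultant_length_law(self):
        # E[ITC] for n uniform phases is ~ sqrt(pi)/(2 sqrt(n))
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(20):
            ph = rng.uniform(0, 2 * np.pi, 200)
            ep = sinusoid_epochs(n_trials=200, phases=ph, duration=1.0)
            _, coeff = morlet_tfr(ep, freqs=np.array([20.0]), wavelet_length=0.5,
                                  output="complex")
            mid = np.argmin(np.abs(ep.times))
            vals.append(itc(coeff)[0, 0, mid])
        expected = np.sqrt(np.pi) / (2 * np.sqrt(200))
        se = np.sqrt((1 - np.pi / 4) / 200) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(expected, abs=4 * se)

    def test_common_phase_rotation_invariance(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=(8, 2, 3, 5)) + 1j * rng.normal(size=(8, 2, 3, 5))
        assert np.allclose(itc(w), itc(w * np.exp(1j * 0.7)))

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            itc(np.ones((1, 2, 3, 4), dtype=complex))


class TestBaselineCorrect:
    def test_stationary_signal_centers_at_zero(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 6, 1 / FS)
        ep = EpochSet(data=rng.normal(size=(15, 2, t.size)), times=t - 3,
                      sample_rate=FS, alignment="consecutive")
        tfr = morlet_tfr(ep, freqs=np.array([10.0, 30.0]), wavelet_length=0.3)
        corr = baseline_correct(tfr, (-2.5, 2.5))
        mask = corr.time_mask(-2.5, 2.5)
        assert np.abs(corr.power[..., mask].mean(axis=-1)).max() < 1e-12 \
            or np.allclose(corr.power[..., mask].mean(axis=-1), 0, atol=1e-9)

    def test_idempotent(self):
        ep = sinusoid_epochs(n_trials=3)
        tfr = morlet_tfr(ep, freqs=np.array([20.0]), wavelet_length=0.5)
        once = baseline_correct(tfr, (-1.0, 1.0))
        twice = baseline_correct(once, (-1.0, 1.0))
        assert np.allclose(once.power, twice.power, atol=1e-12)

    def test_injected_step_recovered(self):
        t = np.arange(0, 6, 1 / FS) - 3
        base = np.cos(2 * np.pi * 20 * t)
        stepped = np.where(t > 1.0, np.sqrt(2.0) * base, base)  # power doubles
        ep = EpochSet(data=stepped[None, None, :], times=t, sample_rate=FS,
                      alignment="consecutive")
        tfr = morlet_tfr(ep, freqs=np.array([20.0]), wavelet_length=0.3)
        corr = baseline_correct(tfr, (-2.5, 0.5))
        p0 = tfr.power[0, 0, tfr.time_mask(-2.5, 0.5)].mean()
        step_val = corr.power[0, 0, corr.time_mask(1.5, 2.5)].mean()
        assert step_val == pytest.approx(p0, rel=0.02)  # +P on top of baseline P

    def test_window_outside_epoch_rejected(self):
        tfr = morlet_tfr(sinusoid_epochs(), freqs=np.array([20.0]),
                         wavelet_length=0.5)
        with pytest.raises(ValueError):
            baseline_correct(tfr, (10.0, 11.0))


class TestSegmentSpectrum:
    def _epochs_with(self, freq, n_trials=5, amp=1.0):
        rng = np.random.default_rng(0)
        t = np.arange(0, 1.0, 1 / FS) - 0.2
        data = amp * np.cos(2 * np.pi * freq * t[None, None, :]
                            + rng.uniform(0, 2 * np.pi, (n_trials, 1, 1)))
        return EpochSet(data=np.repeat(data, 2, axis=1), times=t, sample_rate=FS,
                        alignment="train_offset")

    def test_grid_is_natural_dft_grid(self):
        spec = segment_spectrum(self._epochs_with(12.9))
        assert np.allclose(np.diff(spec.freqs), 1.0 / 0.155, atol=1e-6)
        assert spec.freqs[0] == pytest.approx(1.0 / 0.155, abs=1e-6)
        assert len(spec.freqs) == 9

    def test_sinusoid_at_bin2_peaks_there(self):
        spec = segment_spectrum(self._epochs_with(12.9))
        assert spec.power[0].argmax() == 1  # k=2 is index 1 on the k=1..9 grid

    def test_zero_signal_zero_spectrum(self):
        t = np.arange(0, 1.0, 1 / FS) - 0.2
        ep = EpochSet(data=np.zeros((3, 2, t.size)), times=t, sample_rate=FS,
                      alignment="train_offset")
        assert segment_spectrum(ep).power.max() == 0.0

    def test_parseval_relation(self):
        """Total periodogram power equals the mean square of the tapered,
        demeaned segment (periodogram normalization)."""
        from scipy.signal import periodogram

        rng = np.random.default_rng(5)
        t = np.arange(0, 1.0, 1 / FS) - 0.2
        x = rng.normal(size=t.size)
        idx = (t >= 0.005 - 1e-12) & (t < 0.160 - 1e-12)
        f, pxx = periodogram(x[idx], fs=FS, window="hann", detrend="constant")
        seg = x[idx] - x[idx].mean()
        from scipy.signal.windows import hann

        w = hann(idx.sum(), sym=False)
        xw = seg * w
        direct = np.sum(xw**2) / np.sum(w**2)
        assert np.sum(pxx) * (FS / idx.sum()) == pytest.approx(direct, rel=1e-9)

    def test_window_past_epoch_rejected(self):
        t = np.arange(0, 0.1, 1 / FS)
        ep = EpochSet(data=np.zeros((3, 1, t.size)), times=t, sample_rate=FS,
                      alignment="train_offset")
        with pytest.raises(ValueError):
            segment_spectrum(ep, window=(0.005, 0.160))
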