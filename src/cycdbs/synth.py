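"""Synthetic cyclic-DBS cohort generator with known ground truth.

Each simulated subject is a bilateral sensor array recording containing:

* 1/f background noise, independent per channel,
* a narrowband beta oscillation per hemisphere (band-pass filtered Gaussian
  noise, so the oscillation has a realistic drifting phase), projected onto a
  "sensorimotor" ROI channel group and, more weakly, the remaining channels
  of that hemisphere,
* during stimulation ON periods: a biphasic pulse-train artifact projected
  onto a disjoint "wire path" channel group, plus a pulse-locked evoked field
  on the left ROI channels (the basis for ROI selection),
* after each train offset, one of two response modes:

  - ``induced``: the left-hemisphere beta *envelope* is multiplied by
    ``1 + A * exp(-t/tau)`` (and by ``1 + A`` during ON), raising beta power
    without imposing the stimulus phase,
  - ``entrainment``: a decaying sinusoid at the stimulation frequency,
    phase-continuous with the final pulse of the train, is added to the left
    ROI channels, producing phase alignment across trains.

Finger tapping is generated as a gamma-renewal point process inside the
green-cue windows of the tapping task, with rate
``tap_rate_base - li_tap_coupling * LI(t)`` so that stronger left-hemisphere
beta dominance slows tapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from .core import EventTable, RawRecording, SensorLayout, StimSchedule, build_mirror_map

import pandas as pd


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cyclic-DBS experiment.

    Amplitudes are in the same arbitrary field units as the recording; the
    background 1/f noise has unit standard deviation per channel, so
    ``beta_amplitude`` etc. are effectively SNR parameters.
    """

    n_subjects: int = 14
    n_channels_per_hemisphere: int = 10
    sample_rate: float = 1000.0  # Hz
    duration: float = 480.0  # s; one resting-state block (8 min)
    tapping_duration: float = 175.0  # s; 7 blocks x (10 s red + 15 s green)
    stim_frequencies: tuple = (10.0, 16.0, 20.0, 26.0, 30.0)
    on_duration: float = 5.0
    off_duration: float = 3.0
    # oscillation and noise
    beta_center_freq: float = 15.0  # Hz
    beta_bandwidth: float = 4.0  # Hz full width
    beta_amplitude: tuple = (1.0, 1.0)  # (left, right) source SD in noise-SD units
    alpha_center_freq: float = 10.0  # Hz; bilateral symmetric background rhythm
    alpha_bandwidth: float = 4.0
    alpha_amplitude: float = 2.0  # same in both hemispheres (no lateralization)
    noise_exponent: float = 1.5  # 1/f^exponent power slope
    noise_amplitude: float = 1.0
    noise_floor: float = 0.3  # flat (sensor) noise SD relative to noise_amplitude
    roi_channel_weight: float = 1.0  # beta projection onto ROI channels
    background_channel_weight: float = 0.25  # beta projection onto non-ROI channels
    n_roi_channels: int = 5  # per hemisphere
    # stimulation response
    response_mode: str = "induced"  # {"induced", "entrainment", "none"}
    aftereffect_gain: float = 0.6  # A, dimensionless envelope gain
    aftereffect_gain_spread: float = 0.5  # between-subject SD as a fraction of A
    aftereffect_tau: float = 0.15  # s; power decays below noise by ~400 ms
    # artifacts and evoked fields
    artifact_amplitude: float = 40.0
    n_wire_channels: int = 3  # right posterior "wire path" group
    evoked_gain: float = 0.75  # pulse-locked evoked field peak on left ROI channels
    # behavior
    tap_rate_base: float = 120.0  # taps/min
    tap_rate_subject_sd: float = 6.0  # between-subject SD of the base rate
    li_tap_coupling: float = 20.0  # taps/min per unit LI
    subject_li_sd: float = 0.12  # between-subject SD of baseline beta LI
    tap_shape: float = 4.0  # gamma renewal shape; 1 = Poisson (exponential)
    cue_red_duration: float = 10.0
    cue_green_duration: float = 15.0
    n_tap_blocks: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.aftereffect_gain < 0:
            raise ValueError("aftereffect_gain must be >= 0")
        if self.aftereffect_tau <= 0:
            raise ValueError("aftereffect_tau must be > 0")
        if self.response_mode not in ("induced", "entrainment", "none"):
            raise ValueError(f"unknown response_mode {self.response_mode!r}")
        if min(self.beta_amplitude) < 0 or self.artifact_amplitude < 0 or self.evoked_gain < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def beta_band(self) -> tuple:
        half = self.beta_bandwidth / 2.0
        return (self.beta_center_freq - half, self.beta_center_freq + half)

    @property
    def alpha_band(self) -> tuple:
        half = self.alpha_bandwidth / 2.0
        return (self.alpha_center_freq - half, self.alpha_center_freq + half)


@dataclass
class GroundTruth:
    """Simulation ledger stored alongside each synthetic recording."""

    subject_index: int
    stim_frequency: Optional[float]
    response_mode: str
    aftereffect_gain: float  # this subject's injected A
    aftereffect_tau: float
    train_offsets: np.ndarray = field(default_factory=lambda: np.array([]))
    roi_left: list = field(default_factory=list)
    roi_right: list = field(default_factory=list)
    wire_channels: list = field(default_factory=list)
    baseline_li: float = 0.0  # injected noise-free beta LI at rest
    delta_li: float = 0.0  # injected noise-free LI shift in the after-effect window
    segment_rates: Optional[pd.DataFrame] = None  # per tapping segment true rates

    def to_dict(self) -> dict:
        d = {
            "subject_index": self.subject_index,
            "stim_frequency": self.stim_frequency,
            "response_mode": self.response_mode,
            "aftereffect_gain": self.aftereffect_gain,
            "aftereffect_tau": self.aftereffect_tau,
            "train_offsets": np.asarray(self.train_offsets).tolist(),
            "roi_left": list(self.roi_left),
            "roi_right": list(self.roi_right),
            "wire_channels": list(self.wire_channels),
            "baseline_li": self.baseline_li,
            "delta_li": self.delta_li,
        }
        if self.segment_rates is not None:
            d["segment_rates"] = self.segment_rates.to_dict(orient="list")
        return d


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

def make_schedule(
    duration: float,
    stim_frequency: Optional[float],
    on: float = 5.0,
    off: float = 3.0,
    pulse_amplitude: float = 3.0,
) -> StimSchedule:
    """Tile ``[0, duration]`` with ON/OFF cycles; a train is kept if its ON
    period completes, and the schedule is flagged partial when the final OFF
    period is cut short."""
    if duration < on:
        raise ValueError("duration too short for a single train")
    period = on + off
    n = int(np.floor((duration - on) / period)) + 1
    onsets = np.arange(n) * period
    offsets = onsets + on
    partial = bool(onsets[-1] + period > duration + 1e-9)
    return StimSchedule(
        stim_frequency=stim_frequency,
        on_duration=on,
        off_duration=off,
        pulse_amplitude=pulse_amplitude,
        train_onsets=onsets,
        train_offsets=offsets,
        partial_last_cycle=partial,
    )


def pulse_times(schedule: StimSchedule) -> np.ndarray:
    """Pulse times of the cyclic stimulation.

    Pulses are spaced 1/f within each train, with the last pulse of every
    train falling exactly on the train offset (the alignment point of the
    analysis).
    """
    if schedule.stim_frequency is None:
        return np.array([])
    f = schedule.stim_frequency
    k = np.arange(1, int(round(schedule.on_duration * f)) + 1)
    return (schedule.train_onsets[:, None] + k[None, :] / f).ravel()


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

def default_layout(n_per_hemisphere: int = 10, n_roi: int = 5, n_wire: int = 3) -> SensorLayout:
    """Bilateral two-column grid layout mirrored across the posteroanterior midline.

    Channels ``L00..`` / ``R00..`` are ordered anterior-to-posterior within
    two columns per hemisphere.  The first ``n_roi`` left channels (and their
    mirrors) form the "sensorimotor" group carrying the strong beta
    projection; the last ``n_wire`` right channels (posterior) form the
    artifact "wire path" group.
    """
    n_rows = int(np.ceil(n_per_hemisphere / 2))
    pos_hemi = []
    for i in range(n_per_hemisphere):
        col, row = divmod(i, n_rows)
        pos_hemi.append((1.0 + col, float(n_rows - 1 - row)))
    pos_hemi = np.asarray(pos_hemi, dtype=float)
    ids, pos, hemi = [], [], []
    for i in range(n_per_hemisphere):
        ids.append(f"L{i:02d}")
        pos.append((-pos_hemi[i, 0], pos_hemi[i, 1]))
        hemi.append("left")
    for i in range(n_per_hemisphere):
        ids.append(f"R{i:02d}")
        pos.append((pos_hemi[i, 0], pos_hemi[i, 1]))
        hemi.append("right")
    layout = SensorLayout(
        channel_ids=ids,
        positions=np.asarray(pos),
        hemisphere=np.asarray(hemi, dtype=object),
    )
    layout.adjacency_from_positions(max_dist=1.5)
    return build_mirror_map(layout)


def roi_channels(layout: SensorLayout, n_roi: int) -> tuple:
    left = [c for c in layout.channel_ids if c.startswith("L")][:n_roi]
    right = [layout.mirror_map[c] for c in left]
    return left, right


def wire_channels(layout: SensorLayout, n_wire: int) -> list:
    right = [c for c in layout.channel_ids if c.startswith("R")]
    return right[-n_wire:]


# ---------------------------------------------------------------------------
# Signal components
# ---------------------------------------------------------------------------

def one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                     exponent: float, sample_rate: float) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^exponent, unit SD per channel."""
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    scale = np.zeros(n_freq)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, n_freq))
            + 1j * rng.standard_normal((n_channels, n_freq))) * scale
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def narrowband_source(rng: np.random.Generator, n_samples: int, band: tuple,
                      sample_rate: float) -> np.ndarray:
    """Unit-SD beta source: 4th-order zero-phase band-pass filtered white noise."""
    sos = signal.butter(2, band, btype="bandpass", fs=sample_rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x / x.std()


def _evoked_kernel(sample_rate: float) -> np.ndarray:
    """Unit-peak evoked-field kernel: brief Gaussian bump peaking ~8 ms after the pulse.

    Kept short (gone by ~16 ms) so that the response to the final pulse of a
    train contributes negligibly to the 5-160 ms after-effect window."""
    t = np.arange(0, int(round(0.016 * sample_rate)) + 1) / sample_rate
    k = np.exp(-((t - 0.008) ** 2) / (2 * 0.0025**2))
    return k / k.max()


def _envelope_gain(times: np.ndarray, schedule: StimSchedule, gain: float, tau: float) -> np.ndarray:
    """Multiplicative beta-envelope gain: 1 + A during ON, decaying 1 + A e^(-t/tau) after offsets."""
    g = np.ones_like(times)
    if gain == 0 or schedule.stim_frequency is None:
        return g
    for onset, offset in schedule.on_intervals():
        on = (times >= onset) & (times < offset)
        g[on] = 1.0 + gain
        post = times >= offset
        nxt = schedule.train_onsets[schedule.train_onsets > offset]
        if nxt.size:
            post &= times < nxt[0]
        g[post] = 1.0 + gain * np.exp(-(times[post] - offset) / tau)
    return g


# ---------------------------------------------------------------------------
# Subject simulation
# ---------------------------------------------------------------------------

def _li_to_amplitude_ratio(li: float) -> float:
    """Amplitude ratio left/right producing a noise-free power LI of ``li``."""
    li = float(np.clip(li, -0.95, 0.95))
    return float(np.sqrt((1.0 + li) / (1.0 - li)))


def _noise_free_li(p_left: float, p_right: float) -> float:
    total = p_left + p_right
    return (p_left - p_right) / total if total > 0 else 0.0


def simulate_subject(
    config: SimulationConfig,
    subject_index: int = 0,
    stim_frequency: Optional[float] = None,
    duration: Optional[float] = None,
    aftereffect_gain: Optional[float] = None,
    baseline_li: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> RawRecording:
    """Simulate one recording (one subject, one condition).

    ``stim_frequency=None`` yields the DBS-OFF baseline.  The injected
    per-subject after-effect gain defaults to ``config.aftereffect_gain``;
    cohort simulation passes subject-specific draws.  Identical inputs and
    seed give bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1000 * subject_index)
    if config.response_mode == "entrainment" and stim_frequency is None:
        raise ValueError("entrainment mode requires a stimulation frequency")
    if duration is None:
        duration = config.duration
    A = config.aftereffect_gain if aftereffect_gain is None else aftereffect_gain

    fs = config.sample_rate
    n_samples = int(round(duration * fs))
    times = np.arange(n_samples) / fs
    layout = default_layout(config.n_channels_per_hemisphere,
                            config.n_roi_channels, config.n_wire_channels)
    roi_l, roi_r = roi_channels(layout, config.n_roi_channels)
    wires = wire_channels(layout, config.n_wire_channels)

    data = config.noise_amplitude * one_over_f_noise(
        rng, layout.n_channels, n_samples, config.noise_exponent, fs
    )
    if config.noise_floor > 0:
        # flat instrument-noise floor; keeps high-frequency bins from being
        # dominated by spectral leakage of the neural oscillations
        data += (config.noise_amplitude * config.noise_floor
                 * rng.standard_normal(data.shape))

    # hemisphere beta sources with subject-specific amplitude asymmetry
    ratio = _li_to_amplitude_ratio(baseline_li)
    amp_l = config.beta_amplitude[0] * ratio
    amp_r = config.beta_amplitude[1] / ratio
    beta_l = narrowband_source(rng, n_samples, config.beta_band, fs)
    beta_r = narrowband_source(rng, n_samples, config.beta_band, fs)

    schedule = None
    if stim_frequency is not None:
        schedule = make_schedule(duration, stim_frequency,
                                 config.on_duration, config.off_duration)
        if config.response_mode == "induced":
            beta_l = beta_l * _envelope_gain(times, schedule, A, config.aftereffect_tau)

    # bilateral, non-lateralized alpha rhythm (independent source per hemisphere)
    alpha_src = {}
    if config.alpha_amplitude > 0:
        alpha_src["left"] = narrowband_source(rng, n_samples, config.alpha_band, fs)
        alpha_src["right"] = narrowband_source(rng, n_samples, config.alpha_band, fs)

    weights = np.full(layout.n_channels, config.background_channel_weight)
    for c in roi_l + roi_r:
        weights[layout.index(c)] = config.roi_channel_weight
    for i, (cid, h) in enumerate(zip(layout.channel_ids, layout.hemisphere)):
        src = beta_l * amp_l if h == "left" else beta_r * amp_r
        data[i] += weights[i] * src
        if alpha_src and h in alpha_src:
            data[i] += weights[i] * config.alpha_amplitude * alpha_src[h]

    events = []
    gt = GroundTruth(
        subject_index=subject_index,
        stim_frequency=stim_frequency,
        response_mode=config.response_mode if stim_frequency is not None else "none",
        aftereffect_gain=A,
        aftereffect_tau=config.aftereffect_tau,
        roi_left=roi_l,
        roi_right=roi_r,
        wire_channels=wires,
        baseline_li=_noise_free_li(amp_l**2, amp_r**2),
    )

    if schedule is not None:
        gt.train_offsets = schedule.train_offsets
        pulses = pulse_times(schedule)
        pulse_idx = np.round(pulses * fs).astype(int)
        pulse_idx = pulse_idx[pulse_idx < n_samples - 1]
        # biphasic single-sample artifact through the wire-path topography
        train = np.zeros(n_samples)
        train[pulse_idx] += config.artifact_amplitude
        train[pulse_idx + 1] -= config.artifact_amplitude
        for c in wires:
            data[layout.index(c)] += train
        # pulse-locked evoked field on the left ROI
        if config.evoked_gain > 0:
            kernel = _evoked_kernel(fs)
            impulses = np.zeros(n_samples)
            impulses[pulse_idx] = 1.0
            evoked = config.evoked_gain * signal.fftconvolve(impulses, kernel)[:n_samples]
            for c in roi_l:
                data[layout.index(c)] += evoked
        # entrainment: decaying sinusoid phase-continuous with the final pulse
        if config.response_mode == "entrainment" and A > 0:
            term = np.zeros(n_samples)
            for offset in schedule.train_offsets:
                post = times >= offset
                dt = times[post] - offset
                # amplitude A in background-noise SD units, phase-continuous
                # with the final pulse of the train
                term[post] += (A * np.exp(-dt / config.aftereffect_tau)
                               * np.cos(2 * np.pi * stim_frequency * dt))
            for c in roi_l:
                data[layout.index(c)] += term

        cond = stim_frequency
        for onset, offset in schedule.on_intervals():
            events.append((onset, schedule.on_duration, "train_onset", cond))
            events.append((offset, 0.0, "train_offset", cond))
        for tp in pulses[pulses < duration]:
            events.append((tp, 0.0, "pulse", cond))

        # noise-free LI shift over the after-effect window (simulation ledger)
        if config.response_mode == "induced":
            t0, t1 = 0.005, 0.160
            tau = config.aftereffect_tau
            gbar = 1.0 + A * tau / (t1 - t0) * (np.exp(-t0 / tau) - np.exp(-t1 / tau))
            pl, pr = amp_l**2, amp_r**2
            gt.delta_li = _noise_free_li(gbar**2 * pl, pr) - _noise_free_li(pl, pr)

    table = EventTable(pd.DataFrame(events, columns=EventTable.COLUMNS)
                       if events else None)
    return RawRecording(
        sample_rate=fs,
        data=data,
        layout=layout,
        events=table,
        schedule=schedule,
        ground_truth=gt.to_dict(),
    )


# ---------------------------------------------------------------------------
# Tapping behavior
# ---------------------------------------------------------------------------

def _gamma_renewal(rng: np.random.Generator, start: float, stop: float,
                   rate_per_s: float, shape: float) -> list:
    """Event times of an equilibrium gamma-interval renewal process on [start, stop).

    The first arrival is drawn from the forward-recurrence (equilibrium)
    distribution so that the expected count equals ``rate * duration``
    regardless of how the observation window is segmented.  For integer
    shape k the equilibrium distribution is a uniform mixture of
    Gamma(1..k) with the same scale.
    """
    if rate_per_s <= 0:
        return []
    scale = 1.0 / (shape * rate_per_s)
    k = int(round(shape))
    if np.isclose(shape, k) and k >= 1:
        first = rng.gamma(rng.integers(1, k + 1), scale)
    else:  # non-integer shape: exponential-equilibrium approximation
        first = rng.exponential(1.0 / rate_per_s)
    taps = []
    t = start + first
    while t < stop:
        taps.append(t)
        t += rng.gamma(shape, scale)
    return taps


def _intersect(window: tuple, intervals: np.ndarray) -> list:
    """Sub-intervals of `window` covered by `intervals` plus the uncovered rest."""
    a, b = window
    covered = []
    for lo, hi in intervals:
        lo, hi = max(lo, a), min(hi, b)
        if hi > lo:
            covered.append((lo, hi))
    covered.sort()
    gaps, prev = [], a
    for lo, hi in covered:
        if lo > prev:
            gaps.append((prev, lo))
        prev = max(prev, hi)
    if prev < b:
        gaps.append((prev, b))
    return covered, gaps


def tapping_cues(config: SimulationConfig) -> EventTable:
    """Red/green fixation-cross cue sequence of the tapping task."""
    rows = []
    t = 0.0
    for _ in range(config.n_tap_blocks):
        rows.append((t, config.cue_red_duration, "cue_red", "task"))
        t += config.cue_red_duration
        rows.append((t, config.cue_green_duration, "cue_green", "task"))
        t += config.cue_green_duration
    return EventTable(pd.DataFrame(rows, columns=EventTable.COLUMNS))


def simulate_tapping(
    schedule: Optional[StimSchedule],
    config: SimulationConfig,
    subject_li: float = 0.0,
    delta_li: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    base_rate: Optional[float] = None,
) -> tuple:
    """Simulate the finger-tapping task for one recording.

    Taps occur only inside green-cue windows, as a gamma-interval renewal
    process whose rate is ``tap_rate_base - li_tap_coupling * LI(t)`` with
    ``LI(t) = subject_li (+ delta_li during stimulation ON)``.  Negative
    rates are clipped at zero.  Returns ``(EventTable, segment_rates)`` where
    the second element is the per-segment ground-truth rate table.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if base_rate is None:
        base_rate = config.tap_rate_base
    cues = tapping_cues(config)
    on_intervals = schedule.on_intervals() if schedule is not None else np.zeros((0, 2))
    rows, seg_rows = [], []
    for green in cues.windows("cue_green"):
        on_segs, off_segs = _intersect(tuple(green), on_intervals)
        for state, segs in (("on", on_segs), ("off", off_segs)):
            li = subject_li + (delta_li if state == "on" else 0.0)
            rate = max(0.0, base_rate - config.li_tap_coupling * li)
            for lo, hi in segs:
                for t in _gamma_renewal(rng, lo, hi, rate / 60.0, config.tap_shape):
                    rows.append((t, 0.0, "tap", state))
                seg_rows.append({"start": lo, "stop": hi, "state": state,
                                 "true_rate": rate})
    taps = EventTable(pd.DataFrame(rows, columns=EventTable.COLUMNS)
                      if rows else None)
    events = EventTable.concat([cues, taps])
    return events, pd.DataFrame(seg_rows)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """All simulated recordings and ground truth for one subject."""

    subject_index: int
    aftereffect_gain: float
    baseline_li: float
    baseline_rest: Optional[RawRecording] = None
    rest: dict = field(default_factory=dict)  # stim freq -> RawRecording
    tapping_events: dict = field(default_factory=dict)  # condition -> EventTable
    tapping_rest_events: Optional[EventTable] = None
    tapping_meg: dict = field(default_factory=dict)  # condition -> RawRecording
    segment_rates: dict = field(default_factory=dict)  # condition -> DataFrame
    delta_li: float = 0.0


def simulate_cohort(
    config: SimulationConfig,
    include_rest: bool = True,
    include_tapping: bool = True,
    include_tapping_meg: bool = False,
) -> list:
    """Simulate a cohort of subjects across all conditions.

    Per-subject after-effect gains are drawn as
    ``A_i = max(0, Normal(A, spread * A))`` and baseline lateralization as
    ``Normal(0, subject_li_sd)``, so that across subjects the injected LI
    shift and the tap-rate change are negatively correlated whenever
    ``li_tap_coupling > 0``.  All per-recording seeds derive deterministically
    from ``config.seed``.
    """
    if config.n_subjects < 2:
        raise ValueError("cohort needs at least 2 subjects")
    master = np.random.default_rng(config.seed)
    cohort = []
    for s in range(config.n_subjects):
        gain = config.aftereffect_gain
        if config.aftereffect_gain_spread > 0 and gain > 0:
            gain = max(0.0, master.normal(gain, config.aftereffect_gain_spread * gain))
        li0 = master.normal(0.0, config.subject_li_sd) if config.subject_li_sd > 0 else 0.0
        base_rate = config.tap_rate_base
        if config.tap_rate_subject_sd > 0:
            base_rate = max(10.0, master.normal(base_rate, config.tap_rate_subject_sd))
        subj = SubjectData(subject_index=s, aftereffect_gain=gain, baseline_li=li0)
        if include_rest:
            rng = np.random.default_rng(master.integers(2**31))
            subj.baseline_rest = simulate_subject(
                config, s, stim_frequency=None, baseline_li=li0, rng=rng)
            for f in config.stim_frequencies:
                rng = np.random.default_rng(master.integers(2**31))
                rec = simulate_subject(config, s, stim_frequency=f,
                                       aftereffect_gain=gain, baseline_li=li0, rng=rng)
                subj.rest[f] = rec
                subj.delta_li = rec.ground_truth["delta_li"]
        else:
            # ledger-only delta for behavior-level simulations
            t0, t1, tau = 0.005, 0.160, config.aftereffect_tau
            gbar = 1.0 + gain * tau / (t1 - t0) * (np.exp(-t0 / tau) - np.exp(-t1 / tau))
            r = _li_to_amplitude_ratio(li0)
            pl = (config.beta_amplitude[0] * r) ** 2
            pr = (config.beta_amplitude[1] / r) ** 2
            subj.delta_li = (_noise_free_li(gbar**2 * pl, pr) - _noise_free_li(pl, pr))
        if include_tapping:
            rng = np.random.default_rng(master.integers(2**31))
            subj.tapping_rest_events, _ = simulate_tapping(
                None, config, subject_li=li0, rng=rng, base_rate=base_rate)
            for f in config.stim_frequencies:
                sched = make_schedule(config.tapping_duration, f,
                                      config.on_duration, config.off_duration)
                rng = np.random.default_rng(master.integers(2**31))
                # during-ON LI shift: same mechanism as the after-effect, at full gain
                pl = (config.beta_amplitude[0] * _li_to_amplitude_ratio(li0)) ** 2
                pr = (config.beta_amplitude[1] / _li_to_amplitude_ratio(li0)) ** 2
                dli_on = (_noise_free_li((1 + gain) ** 2 * pl, pr)
                          - _noise_free_li(pl, pr))
                ev, seg = simulate_tapping(sched, config, subject_li=li0,
                                           delta_li=dli_on, rng=rng,
                                           base_rate=base_rate)
                subj.tapping_events[f] = ev
                subj.segment_rates[f] = seg
                if include_tapping_meg:
                    rng2 = np.random.default_rng(master.integers(2**31))
                    meg = simulate_subject(config, s, stim_frequency=f,
                                           duration=config.tapping_duration,
                                           aftereffect_gain=gain,
                                           baseline_li=li0, rng=rng2)
                    meg.events = EventTable.concat([meg.events, ev])
                    subj.tapping_meg[f] = meg
        cohort.append(subj)
    return cohort
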