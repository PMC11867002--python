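"""Domain types and container I/O shared by all analysis stages.

Conventions
-----------
* Sensor coordinates are 2-D: x increases from left to right (x > 0 is the
  right hemisphere), y from posterior to anterior.  Midline channels
  (|x| < 1e-9) take part in neither mirroring nor lateralization.
* All time windows are half-open ``[start, stop)`` and expressed in seconds.
* The native raw container is a raw float32 binary matrix (channel-major)
  plus a JSON header and a tab-separated event table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

EVENT_TYPES = ("train_onset", "train_offset", "pulse", "tap", "cue_green", "cue_red")

MIDLINE_TOL = 1e-9
MIRROR_TOL = 1e-6


class FormatError(ValueError):
    """Raised when a container file is malformed or incomplete."""


class MirrorError(ValueError):
    """Raised when left/right channels cannot be paired across the midline."""


# ---------------------------------------------------------------------------
# Sensor layout
# ---------------------------------------------------------------------------

@dataclass
class SensorLayout:
    """2-D sensor array with hemisphere labels, adjacency, and midline mirror pairing.

    Parameters
    ----------
    channel_ids : list of str
    positions : (n_channels, 2) array
        x = left(-) to right(+), y = posterior to anterior, arbitrary units.
    hemisphere : (n_channels,) array of {"left", "right", "midline"}
    adjacency : (n_channels, n_channels) bool array
        Symmetric, irreflexive neighbor relation.
    mirror_map : dict
        Maps each left channel id to its right-hemisphere counterpart.
    """

    channel_ids: list
    positions: np.ndarray
    hemisphere: np.ndarray
    adjacency: Optional[np.ndarray] = None
    mirror_map: Optional[dict] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        n = len(self.channel_ids)
        if self.positions.shape != (n, 2):
            raise FormatError(f"positions must be ({n}, 2), got {self.positions.shape}")
        if self.hemisphere.shape != (n,):
            raise FormatError("hemisphere labels must match channel count")
        if self.adjacency is not None:
            self.adjacency = np.asarray(self.adjacency, dtype=bool)
            if self.adjacency.shape != (n, n):
                raise FormatError("adjacency must be n_channels x n_channels")
            if not np.array_equal(self.adjacency, self.adjacency.T):
                raise FormatError("adjacency must be symmetric")
            if self.adjacency.diagonal().any():
                raise FormatError("adjacency must be irreflexive")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def index(self, channel_id: str) -> int:
        return self.channel_ids.index(channel_id)

    def channels_of(self, hemi: str) -> list:
        return [c for c, h in zip(self.channel_ids, self.hemisphere) if h == hemi]

    def adjacency_from_positions(self, max_dist: float) -> np.ndarray:
        """Build a distance-threshold neighbor graph (symmetric, irreflexive)."""
        d = np.linalg.norm(self.positions[:, None, :] - self.positions[None, :, :], axis=-1)
        adj = (d > 0) & (d <= max_dist)
        self.adjacency = adj
        return adj


def build_mirror_map(layout: SensorLayout) -> SensorLayout:
    """Pair each left channel with the right channel nearest to its x-negated position.

    The pairing realizes mirroring of a left-hemisphere ROI across the
    posteroanterior midline of the sensor array.  Raises :class:`MirrorError`
    when left and right channel counts differ or when the greedy
    nearest-neighbor assignment would reuse a right channel.
    """
    left = [i for i, h in enumerate(layout.hemisphere) if h == "left"]
    right = [i for i, h in enumerate(layout.hemisphere) if h == "right"]
    if len(left) != len(right):
        raise MirrorError(
            f"unequal hemisphere channel counts: {len(left)} left vs {len(right)} right"
        )
    mirror = {}
    taken = set()
    # process left channels in order of best-match confidence (smallest residual
    # first) so that jitter cannot steal a partner from a better-matching channel
    mirrored = layout.positions[left] * np.array([-1.0, 1.0])
    rpos = layout.positions[right]
    d = np.linalg.norm(mirrored[:, None, :] - rpos[None, :, :], axis=-1)
    order = np.argsort(d.min(axis=1))
    unmatched = []
    for li in order:
        ranked = np.argsort(d[li])
        ri = next((r for r in ranked if r not in taken), None)
        if ri is None:
            unmatched.append(layout.channel_ids[left[li]])
            continue
        taken.add(ri)
        mirror[layout.channel_ids[left[li]]] = layout.channel_ids[right[ri]]
    if unmatched:
        raise MirrorError(f"unmatched left channels: {unmatched}")
    layout.mirror_map = mirror
    return layout


# ---------------------------------------------------------------------------
# Stimulation schedule and events
# ---------------------------------------------------------------------------

@dataclass
class StimSchedule:
    """Cyclic stimulation timing: trains of `on_duration` s separated by `off_duration` s."""

    stim_frequency: Optional[float]  # Hz; None for the DBS-OFF baseline
    on_duration: float = 5.0
    off_duration: float = 3.0
    pulse_amplitude: float = 3.0  # mA, metadata only
    train_onsets: np.ndarray = field(default_factory=lambda: np.array([]))
    train_offsets: np.ndarray = field(default_factory=lambda: np.array([]))
    partial_last_cycle: bool = False

    def __post_init__(self):
        self.train_onsets = np.asarray(self.train_onsets, dtype=float)
        self.train_offsets = np.asarray(self.train_offsets, dtype=float)
        if self.train_onsets.size:
            if not np.all(np.diff(self.train_onsets) > 0):
                raise ValueError("train onsets must be strictly increasing")
            if np.any(self.train_offsets[:-1] > self.train_onsets[1:]):
                raise ValueError("trains must be disjoint")

    @property
    def n_trains(self) -> int:
        return len(self.train_onsets)

    def on_intervals(self) -> np.ndarray:
        """(n, 2) array of [onset, offset) ON intervals."""
        return np.column_stack([self.train_onsets, self.train_offsets])

    def off_intervals(self, duration: Optional[float] = None) -> np.ndarray:
        """(n, 2) array of pause intervals following each train."""
        stops = np.append(self.train_onsets[1:], self.train_offsets[-1] + self.off_duration)
        if duration is not None:
            stops = np.minimum(stops, duration)
        return np.column_stack([self.train_offsets, stops])


class EventTable:
    """Thin wrapper around a DataFrame of (onset, duration, event_type, condition)."""

    COLUMNS = ["onset", "duration", "event_type", "condition"]

    def __init__(self, df: Optional[pd.DataFrame] = None):
        if df is None:
            df = pd.DataFrame(columns=self.COLUMNS)
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"event table missing columns: {missing}")
        df = df[self.COLUMNS].copy()
        df["onset"] = df["onset"].astype(float)
        df["duration"] = df["duration"].astype(float)
        if (df["duration"] < 0).any():
            raise FormatError("event durations must be >= 0")
        for etype, grp in df.groupby("event_type"):
            if not grp["onset"].is_monotonic_increasing:
                df = df.sort_values(["event_type", "onset"], kind="stable")
                break
        self.df = df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    def __eq__(self, other):
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.df.equals(other.df)

    def of_type(self, event_type: str) -> pd.DataFrame:
        return self.df[self.df["event_type"] == event_type]

    def onsets(self, event_type: str) -> np.ndarray:
        return self.of_type(event_type)["onset"].to_numpy()

    def windows(self, event_type: str) -> np.ndarray:
        """(n, 2) [onset, onset+duration) intervals for an event type."""
        sub = self.of_type(event_type)
        return np.column_stack([sub["onset"], sub["onset"] + sub["duration"]])

    @classmethod
    def concat(cls, tables) -> "EventTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Recordings and epochs
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Continuous multichannel recording with layout and event table."""

    sample_rate: float
    data: np.ndarray  # (n_channels, n_samples)
    layout: SensorLayout
    events: EventTable
    schedule: Optional[StimSchedule] = None
    ground_truth: Optional[dict] = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise FormatError("data must be channels x samples")
        if self.data.shape[0] != self.layout.n_channels:
            raise FormatError(
                f"data has {self.data.shape[0]} channels, layout has {self.layout.n_channels}"
            )
        if not np.isfinite(self.data).all():
            raise FormatError("recording contains non-finite samples")
        if len(self.events) and (self.events.df["onset"].max() > self.duration + 1e-9):
            raise FormatError("event beyond end of recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class EpochSet:
    """Trials x channels x time array, aligned to train offsets or cut consecutively."""

    data: np.ndarray  # (n_trials, n_channels, n_times)
    times: np.ndarray  # s relative to the alignment event
    sample_rate: float
    alignment: str  # "train_offset" or "consecutive"
    condition: object = "baseline"  # stim frequency (Hz) or "baseline"
    kept_trial_ids: Optional[np.ndarray] = None
    layout: Optional[SensorLayout] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise FormatError("epoch data must be trials x channels x time")
        if self.data.shape[2] != self.times.size:
            raise FormatError("times length must match epoch length")
        if self.alignment not in ("train_offset", "consecutive"):
            raise FormatError(f"unknown alignment {self.alignment!r}")
        if self.kept_trial_ids is None:
            self.kept_trial_ids = np.arange(self.data.shape[0])
        else:
            self.kept_trial_ids = np.asarray(self.kept_trial_ids)
        if self.layout is not None and self.data.shape[1] != self.layout.n_channels:
            raise FormatError("epoch channel count inconsistent with layout")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def time_indices(self, start: float, stop: float) -> np.ndarray:
        """Sample indices with start <= t < stop."""
        return np.nonzero((self.times >= start - 1e-12) & (self.times < stop - 1e-12))[0]

    def save_h5(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.create_dataset("times", data=self.times)
            f.attrs["sample_rate"] = self.sample_rate
            f.attrs["alignment"] = self.alignment
            f.attrs["condition"] = str(self.condition)
            f.create_dataset("kept_trial_ids", data=np.asarray(self.kept_trial_ids, dtype=int))

    @classmethod
    def load_h5(cls, path) -> "EpochSet":
        import h5py

        with h5py.File(path, "r") as f:
            cond = f.attrs["condition"]
            try:
                cond = float(cond)
            except ValueError:
                pass
            return cls(
                data=f["data"][()].astype(float),
                times=f["times"][()],
                sample_rate=float(f.attrs["sample_rate"]),
                alignment=str(f.attrs["alignment"]),
                condition=cond,
                kept_trial_ids=f["kept_trial_ids"][()],
            )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable analysis parameters with defaults matching the reference protocol."""

    # time-frequency
    freqs_min: float = 5.0
    freqs_max: float = 60.0
    freqs_step: float = 1.0
    wavelet_length_long: float = 0.5  # s, for display spectra
    wavelet_length_short: float = 0.3  # s, for after-effect analysis
    # epoching
    epoch_half_width: float = 3.5  # s around each train offset
    baseline_epoch_length: float = 7.0  # s, consecutive baseline cuts
    reject_z_threshold: float = 6.0
    # after-effect analysis
    aftereffect_window: tuple = (0.005, 0.160)  # s post-offset
    pause_window: tuple = (0.155, 2.845)  # s, stimulation-pause reference
    cluster_windows: tuple = ((0.155, 0.31), (0.31, 0.465), (0.465, 0.62))
    cluster_band: tuple = (10.0, 23.0)  # Hz
    roi_z_threshold: float = 4.0
    # tapping analysis
    tapping_band: tuple = (14.0, 18.0)  # Hz
    tapping_exclude_condition: float = 16.0  # Hz
    tapping_on_margin: float = 0.5  # s after train onset before power counts as ON
    # statistics
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    n_permutations: int = 10000  # cap; exhaustive when 2**n <= max_exhaustive
    max_exhaustive: int = 16384
    seed: int = 0

    def freqs(self) -> np.ndarray:
        return np.arange(self.freqs_min, self.freqs_max + 1e-9, self.freqs_step)

    def validate(self):
        for w in (self.aftereffect_window, self.pause_window, *self.cluster_windows):
            if not w[0] < w[1]:
                raise ValueError(f"window start must precede end: {w}")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for f_ in dataclasses.fields(cls):
            if f_.name in d:
                v = d[f_.name]
                if isinstance(v, list):
                    v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                kwargs[f_.name] = v
        return cls(**kwargs).validate()

    def to_yaml(self, path):
        with open(path, "w") as f:
            yaml.safe_dump(_jsonable(self.to_dict()), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Raw container I/O:  <base>.bin + <base>.json + <base>.events.tsv
# ---------------------------------------------------------------------------

def write_raw(raw: RawRecording, base_path) -> Path:
    """Write a recording to the native container (float32 .bin + .json + .events.tsv)."""
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    raw.data.astype(np.float32).tofile(base.with_suffix(".bin"))
    header = {
        "sample_rate": raw.sample_rate,
        "n_channels": raw.layout.n_channels,
        "n_samples": raw.n_samples,
        "channel_ids": list(raw.layout.channel_ids),
        "positions": raw.layout.positions.tolist(),
        "hemisphere": list(raw.layout.hemisphere),
        "adjacency_pairs": (
            [[int(i), int(j)] for i, j in zip(*np.nonzero(np.triu(raw.layout.adjacency)))]
            if raw.layout.adjacency is not None
            else None
        ),
        "mirror_map": raw.layout.mirror_map,
        "schedule": (
            None
            if raw.schedule is None
            else {
                "stim_frequency": raw.schedule.stim_frequency,
                "on_duration": raw.schedule.on_duration,
                "off_duration": raw.schedule.off_duration,
                "pulse_amplitude": raw.schedule.pulse_amplitude,
                "train_onsets": raw.schedule.train_onsets.tolist(),
                "train_offsets": raw.schedule.train_offsets.tolist(),
                "partial_last_cycle": raw.schedule.partial_last_cycle,
            }
        ),
        "ground_truth": _jsonable(raw.ground_truth) if raw.ground_truth else None,
    }
    with open(base.with_suffix(".json"), "w") as f:
        json.dump(header, f)
    raw.events.to_tsv(base.with_suffix(".events.tsv"))
    return base


def read_raw(base_path) -> RawRecording:
    """Read a recording written by :func:`write_raw`. Round-trips bit-exactly."""
    base = Path(base_path)
    json_path = base.with_suffix(".json")
    if not json_path.exists():
        raise FormatError(f"missing sidecar header {json_path}")
    with open(json_path) as f:
        header = json.load(f)
    for key in ("sample_rate", "n_channels", "n_samples", "channel_ids", "positions", "hemisphere"):
        if key not in header or header[key] is None:
            raise FormatError(f"sidecar header missing field '{key}'")
    n_ch, n_s = int(header["n_channels"]), int(header["n_samples"])
    mat = np.fromfile(base.with_suffix(".bin"), dtype=np.float32)
    if mat.size != n_ch * n_s:
        raise FormatError(
            f"matrix size {mat.size} inconsistent with header {n_ch}x{n_s}"
        )
    adjacency = None
    if header.get("adjacency_pairs") is not None:
        adjacency = np.zeros((n_ch, n_ch), dtype=bool)
        for i, j in header["adjacency_pairs"]:
            adjacency[i, j] = adjacency[j, i] = True
    layout = SensorLayout(
        channel_ids=list(header["channel_ids"]),
        positions=np.asarray(header["positions"], dtype=float),
        hemisphere=np.asarray(header["hemisphere"], dtype=object),
        adjacency=adjacency,
        mirror_map=header.get("mirror_map"),
    )
    events_path = base.with_suffix(".events.tsv")
    events = EventTable.from_tsv(events_path) if events_path.exists() else EventTable()
    schedule = None
    if header.get("schedule") is not None:
        s = header["schedule"]
        schedule = StimSchedule(
            stim_frequency=s["stim_frequency"],
            on_duration=s["on_duration"],
            off_duration=s["off_duration"],
            pulse_amplitude=s["pulse_amplitude"],
            train_onsets=np.asarray(s["train_onsets"], dtype=float),
            train_offsets=np.asarray(s["train_offsets"], dtype=float),
            partial_last_cycle=s.get("partial_last_cycle", False),
        )
    return RawRecording(
        sample_rate=float(header["sample_rate"]),
        data=mat.reshape(n_ch, n_s),
        layout=layout,
        events=events,
        schedule=schedule,
        ground_truth=header.get("ground_truth"),
    )
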