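"""Data model and plain-text IO for synchronized gait recordings.

A trial bundles two uniformly sampled streams recorded against a shared
hardware-trigger clock (t = 0 at the trigger): optical motion-capture marker
trajectories (meters, typically 100 Hz) and foot-mounted IMU channels
(accelerometer in g, gyroscope in deg/s, typically 1000 Hz).  No resampling is
ever performed between the two streams; all downstream comparisons operate on
event times in seconds.

Interchange formats are delimited UTF-8 text (comma or tab, auto-detected),
one header line, first column ``time_s``:

* marker files: columns ``<MARKER>.<X|Y|Z>``
* IMU files: columns ``<H|T>.<ACC|GY>.<X|Y|Z>.<L|R>``
* event files: columns ``time_s,kind,side,source``
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

SIDES = ("L", "R")
EVENT_KINDS = ("IC", "TC")
EVENT_SOURCES = ("OMC", "IMU", "TRUTH")
CONDITIONS = ("FW", "BW")

#: tolerance (s) for declaring the time column of a file uniformly sampled
TIME_REGULARITY_TOL = 1e-6


class FormatError(ValueError):
    """Raised when an interchange file violates the columnar dialect."""


@dataclass(frozen=True)
class TimeSeries:
    """One uniformly sampled scalar channel.

    Sample ``k`` carries the timestamp ``t0 + k / rate`` (half-open sample
    convention: the sample owns ``[t0 + k/rate, t0 + (k+1)/rate)``); event
    times reported by detectors are the timestamps of identified samples.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite samples in channel {self.label!r}")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Record length in seconds (n / rate)."""
        return self.n / self.rate

    @property
    def t_end(self) -> float:
        """Timestamp of the last sample."""
        return self.t0 + (self.n - 1) / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeSeries":
        """Same clock, new samples (used by filters, which must preserve length)."""
        return TimeSeries(values, self.rate, self.t0,
                          self.label if label is None else label)


def trim_edges(ts: TimeSeries, head_s: float = 1.0, tail_s: float = 1.0) -> TimeSeries:
    """Drop the first ``head_s`` and last ``tail_s`` seconds of a record.

    Retained samples are bit-exact copies; only ``t0`` and the length change.
    Defaults implement the standard protocol of discarding the first and last
    second of each 30 s treadmill recording.
    """
    if head_s < 0 or tail_s < 0:
        raise ValueError("trim amounts must be non-negative")
    if head_s + tail_s >= ts.duration:
        raise ValueError(
            f"cannot trim {head_s + tail_s:g} s from a {ts.duration:g} s record")
    eps = 1e-9
    k0 = int(np.ceil(head_s * ts.rate - eps))
    k1 = int(np.floor((ts.n - 1) - tail_s * ts.rate + eps))
    if k1 < k0:
        raise ValueError("trim leaves no samples")
    return TimeSeries(ts.values[k0:k1 + 1].copy(), ts.rate,
                      ts.t0 + k0 / ts.rate, ts.label)


def _check_shared_clock(series: Iterable[TimeSeries], what: str) -> None:
    series = list(series)
    if not series:
        return
    rate0, t00 = series[0].rate, series[0].t0
    for s in series[1:]:
        if s.rate != rate0 or s.t0 != t00:
            raise ValueError(f"{what} channels do not share rate/t0 "
                             f"({s.label!r}: {s.rate} Hz @ {s.t0} s vs {rate0} Hz @ {t00} s)")


@dataclass
class MarkerSet:
    """Marker trajectories: marker name -> axis ('X'/'Y'/'Z') -> TimeSeries (m).

    ``walking_axis`` names the lab axis aligned with the treadmill belt
    (anterior-posterior); ``forward_sign`` is +1 or -1 depending on which way
    along that axis the participant faces.
    """

    markers: dict[str, dict[str, TimeSeries]]
    walking_axis: str = "X"
    forward_sign: int = 1

    def __post_init__(self) -> None:
        if self.walking_axis not in ("X", "Y", "Z"):
            raise ValueError(f"walking_axis must be X/Y/Z, got {self.walking_axis!r}")
        if self.forward_sign not in (1, -1):
            raise ValueError("forward_sign must be +1 or -1")
        _check_shared_clock(
            (ts for axes in self.markers.values() for ts in axes.values()), "marker")

    @property
    def rate(self) -> float:
        return next(iter(self._all_series())).rate

    @property
    def t0(self) -> float:
        return next(iter(self._all_series())).t0

    def _all_series(self):
        for axes in self.markers.values():
            yield from axes.values()

    @property
    def duration(self) -> float:
        return next(iter(self._all_series())).duration

    def ap(self, marker: str) -> TimeSeries:
        """Anterior-posterior (walking-axis) trajectory of one marker."""
        try:
            return self.markers[marker][self.walking_axis]
        except KeyError:
            raise KeyError(f"marker {marker!r} axis {self.walking_axis!r} not present") from None


@dataclass
class ImuRecord:
    """IMU channels keyed ``<H|T>.<ACC|GY>.<X|Y|Z>.<L|R>`` (e.g. ``H.ACC.Z.L``)."""

    channels: dict[str, TimeSeries]

    def __post_init__(self) -> None:
        for key in self.channels:
            _validate_imu_key(key)
        _check_shared_clock(self.channels.values(), "IMU")

    @property
    def rate(self) -> float:
        return next(iter(self.channels.values())).rate

    @property
    def t0(self) -> float:
        return next(iter(self.channels.values())).t0

    def get(self, sensor: str, modality: str, axis: str, side: str) -> TimeSeries:
        key = f"{sensor}.{modality}.{axis}.{side}"
        try:
            return self.channels[key]
        except KeyError:
            raise KeyError(f"IMU channel {key!r} not present") from None


def _validate_imu_key(key: str) -> None:
    parts = key.split(".")
    ok = (len(parts) == 4 and parts[0] in ("H", "T") and parts[1] in ("ACC", "GY")
          and parts[2] in ("X", "Y", "Z") and parts[3] in SIDES)
    if not ok:
        raise FormatError(f"malformed IMU channel key {key!r} "
                          "(expected <H|T>.<ACC|GY>.<X|Y|Z>.<L|R>)")


@dataclass
class Trial:
    """Synchronized marker + IMU bundle for one walking condition."""

    markers: MarkerSet
    imu: ImuRecord
    condition: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.markers.t0 != self.imu.t0:
            raise ValueError("marker and IMU streams must start on the shared trial clock")
        if self.duration <= 0:
            raise ValueError("trial duration must be positive")

    @property
    def duration(self) -> float:
        return min(self.markers.duration,
                   next(iter(self.imu.channels.values())).duration)


@dataclass
class TrialConfig:
    """Declared trial layout: axes, condition, rates, units.

    Units are declared, never inferred: marker positions in meters,
    accelerations in g, angular velocities in deg/s.
    """

    walking_axis: str = "X"
    forward_sign: int = 1
    condition: str = "FW"
    marker_rate: float = 100.0
    imu_rate: float = 1000.0
    marker_units: str = "m"
    acc_units: str = "g"
    gyro_units: str = "deg/s"
    required_markers: tuple[str, ...] = ()
    required_channels: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "TrialConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown trial-config keys: {sorted(unknown)}")
        for key in ("required_markers", "required_channels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# columnar readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str | os.PathLike) -> tuple[pd.DataFrame, float, float]:
    """Read one delimited file, validate the time column, return (df, rate, t0)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise FormatError(f"{path}: first column must be 'time_s'")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least two samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > TIME_REGULARITY_TOL:
        raise FormatError(f"{path}: irregular sampling (steps deviate by more than "
                          f"{TIME_REGULARITY_TOL:g} s)")
    return df, 1.0 / dt, float(t[0])


def _check_rate(found: float, declared: float, path, what: str) -> None:
    if abs(found - declared) > 1e-3 * declared:
        raise FormatError(f"{path}: {what} rate {found:.6g} Hz does not match the "
                          f"declared {declared:g} Hz")


def read_markers(path: str | os.PathLike, config: TrialConfig) -> MarkerSet:
    df, rate, t0 = _read_table(path)
    _check_rate(rate, config.marker_rate, path, "marker")
    markers: dict[str, dict[str, TimeSeries]] = {}
    for col in df.columns[1:]:
        name, dot, axis = col.rpartition(".")
        if not dot or axis not in ("X", "Y", "Z") or not name:
            raise FormatError(f"{path}: malformed marker column {col!r} "
                              "(expected <MARKER>.<X|Y|Z>)")
        markers.setdefault(name, {})[axis] = TimeSeries(
            df[col].to_numpy(dtype=float), config.marker_rate, t0, col)
    missing = [m for m in config.required_markers if m not in markers]
    if missing:
        raise FormatError(f"{path}: declared markers missing: {missing}")
    return MarkerSet(markers, config.walking_axis, config.forward_sign)


def read_imu(path: str | os.PathLike, config: TrialConfig) -> ImuRecord:
    df, rate, t0 = _read_table(path)
    _check_rate(rate, config.imu_rate, path, "IMU")
    channels = {col: TimeSeries(df[col].to_numpy(dtype=float),
                                config.imu_rate, t0, col)
                for col in df.columns[1:]}
    for key in channels:
        _validate_imu_key(key)
    missing = [c for c in config.required_channels if c not in channels]
    if missing:
        raise FormatError(f"{path}: declared IMU channels missing: {missing}")
    return ImuRecord(channels)


def read_trial(marker_path: str | os.PathLike, imu_path: str | os.PathLike,
               config: TrialConfig) -> Trial:
    """Load a synchronized trial from its marker and IMU files."""
    markers = read_markers(marker_path, config)
    imu = read_imu(imu_path, config)
    return Trial(markers, imu, config.condition,
                 metadata={"marker_path": str(marker_path), "imu_path": str(imu_path)})


def write_markers(markers: MarkerSet, path: str | os.PathLike) -> None:
    cols = {"time_s": next(iter(markers._all_series())).times}
    for name in markers.markers:
        for axis, ts in markers.markers[name].items():
            cols[f"{name}.{axis}"] = ts.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def write_imu(imu: ImuRecord, path: str | os.PathLike) -> None:
    cols = {"time_s": next(iter(imu.channels.values())).times}
    cols.update({key: ts.values for key, ts in imu.channels.items()})
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def write_trial(trial: Trial, marker_path: str | os.PathLike,
                imu_path: str | os.PathLike) -> None:
    write_markers(trial.markers, marker_path)
    write_imu(trial.imu, imu_path)


# ---------------------------------------------------------------------------
# gait events
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GaitEvent:
    """One timestamped detection: initial contact (IC) or terminal contact (TC)."""

    time: float
    kind: str
    side: str
    source: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}, got {self.kind!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.source not in EVENT_SOURCES:
            raise ValueError(f"source must be one of {EVENT_SOURCES}, got {self.source!r}")


@dataclass
class EventSeries:
    """Ordered list of gait events for one trial/condition.

    Within each (kind, side, source) stream times must be strictly
    increasing; within a (side, source) stream, IC and TC are expected to
    alternate.  Alternation violations are *reported* by
    :meth:`alternation_violations`, never silently repaired.
    """

    events: list[GaitEvent]
    condition: str | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events)
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        for key in {(e.kind, e.side, e.source) for e in self.events}:
            t = np.array([e.time for e in self.events
                          if (e.kind, e.side, e.source) == key])
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"event times not strictly increasing in stream {key}")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def filter(self, kind: str | None = None, side: str | None = None,
               source: str | None = None) -> "EventSeries":
        sel = [e for e in self.events
               if (kind is None or e.kind == kind)
               and (side is None or e.side == side)
               and (source is None or e.source == source)]
        return EventSeries(sel, self.condition)

    def times(self, kind: str | None = None, side: str | None = None,
              source: str | None = None) -> np.ndarray:
        return np.array([e.time for e in self.filter(kind, side, source)], dtype=float)

    def alternation_violations(self) -> list[str]:
        """Report every place an IC/TC alternation breaks, per (side, source)."""
        msgs = []
        for side in SIDES:
            for source in EVENT_SOURCES:
                stream = [e for e in self.events if e.side == side and e.source == source]
                for a, b in zip(stream, stream[1:]):
                    if a.kind == b.kind:
                        msgs.append(f"consecutive {a.kind} events at t={a.time:.3f} s and "
                                    f"t={b.time:.3f} s (side {side}, source {source})")
        return msgs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": [e.time for e in self.events],
            "kind": [e.kind for e in self.events],
            "side": [e.side for e in self.events],
            "source": [e.source for e in self.events],
        })


def write_events(events: EventSeries, path: str | os.PathLike) -> None:
    """Write an event table (sorted by time; times printed to 1e-6 s)."""
    events.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_events(path: str | os.PathLike, condition: str | None = None) -> EventSeries:
    df = pd.read_csv(path)
    expected = ["time_s", "kind", "side", "source"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: event file must have columns {expected}")
    evts = [GaitEvent(float(r.time_s), str(r.kind), str(r.side), str(r.source))
            for r in df.itertuples(index=False)]
    return EventSeries(evts, condition)
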