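"""Gait-event detectors.

Four detectors are implemented, two per walking direction:

* **Kinematic (OMC)** — extrema of the anterior-posterior displacement of a
  foot marker relative to the pelvis.  Forward walking: relative maxima are
  initial contacts (heel strikes) and relative minima are terminal contacts
  (toe-offs).  Backward walking swaps the labels: the most backward foot
  position is the initial (toe) contact, the most forward the terminal (heel)
  contact.
* **IMU, forward walking** — maxima of the smoothed vertical heel-accelerometer
  channel (H.ACC.Z) are initial contacts; minima of the smoothed heel-gyroscope
  channel (H.GY.Z) are terminal contacts.
* **IMU, backward walking** — maxima of the vertical toe-accelerometer channel
  (T.ACC.Z) are initial contacts; terminal contact is the first local minimum
  of each contiguous run of samples below mean - 1 SD of the channel.

All detectors share one peak engine (:func:`find_extrema`) whose gating
parameters live in :class:`PeakParams`.  Empty detections on non-degenerate
input raise a :class:`DetectionWarning`, never an exception.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from . import preprocessing as prep
from .signals import EventSeries, GaitEvent, MarkerSet, TimeSeries, Trial, trim_edges


class DetectionWarning(UserWarning):
    """Signals an empty or structurally suspect detection (not an error)."""


#: pelvis reference markers: centroid of left/right anterior and posterior
#: superior iliac spines stands in for a full pelvis segment model
DEFAULT_PELVIS_MARKERS = ("ASIS_L", "ASIS_R", "PSIS_L", "PSIS_R")


@dataclass
class PeakParams:
    """Gating parameters for the shared peak engine.

    min_separation
        Minimum time between retained extrema (s).  ``None`` (default)
        resolves to half the dominant stride period estimated from the
        channel autocorrelation, which suppresses noise extrema at slow
        backward speeds without merging strides at fast forward speeds.
    min_prominence
        Required topographic prominence as a fraction of the channel's robust
        amplitude (95th - 5th percentile).
    threshold_sd
        Multiplier for the backward-walking terminal-contact run rule:
        the threshold is mean - threshold_sd * SD of the whole trimmed,
        filtered record (location-invariant, so a constant offset such as
        gravity does not change the rule).
    min_run
        Minimum duration (s) a below-threshold run must last; rejects
        single-sample noise excursions (10 ms = 10 samples at 1000 Hz).
    """

    min_separation: float | None = None
    min_prominence: float = 0.1
    threshold_sd: float = 1.0
    min_run: float = 0.010

    def __post_init__(self) -> None:
        if self.min_separation is not None and self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if not 0 <= self.min_prominence < 1:
            raise ValueError("min_prominence must lie in [0, 1)")
        if self.min_run < 0:
            raise ValueError("min_run must be non-negative")


def relative_displacement(markers: MarkerSet, foot_marker: str,
                          pelvis_markers: Sequence[str]) -> TimeSeries:
    """Anterior-posterior displacement of a foot marker relative to the pelvis.

    Output = forward_sign x (foot AP position - centroid of the pelvis
    markers' AP positions), in meters.  Positive values mean the foot is
    ahead of the pelvis in the facing direction.
    """
    if not pelvis_markers:
        raise ValueError("pelvis marker list must be non-empty")
    foot = markers.ap(foot_marker)
    pelvis = [markers.ap(m) for m in pelvis_markers]
    for p in pelvis:
        if p.rate != foot.rate or p.n != foot.n:
            raise ValueError("mismatched rates/lengths between foot and pelvis markers")
    centroid = np.mean([p.values for p in pelvis], axis=0)
    values = markers.forward_sign * (foot.values - centroid)
    return TimeSeries(values, foot.rate, foot.t0,
                      f"{foot_marker}-pelvis.{markers.walking_axis}")


def estimate_stride_period(ts: TimeSeries, lo_s: float = 0.4,
                           hi_s: float = 4.0) -> float | None:
    """Dominant stride period from the autocorrelation peak in [lo_s, hi_s].

    Returns ``None`` when no positive autocorrelation peak exists in the lag
    range (aperiodic or too-short record).
    """
    x = ts.values - np.mean(ts.values)
    n = x.size
    k_lo = max(1, int(np.ceil(lo_s * ts.rate)))
    k_hi = min(n - 2, int(np.floor(hi_s * ts.rate)))
    if k_hi <= k_lo or not np.any(x):
        return None
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    seg = ac[k_lo:k_hi + 1]
    interior = (seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:]) & (seg[1:-1] > 0)
    idx = np.nonzero(interior)[0] + 1
    if idx.size == 0:
        return None
    best = idx[np.argmax(seg[idx])]
    return (k_lo + best) / ts.rate


def _local_max_indices(x: np.ndarray) -> np.ndarray:
    """Interior local maxima; a plateau resolves to its earliest sample."""
    n = x.size
    idx = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx, dtype=int)


def _resolve_min_separation(ts: TimeSeries, params: PeakParams) -> float:
    if params.min_separation is not None:
        return params.min_separation
    period = estimate_stride_period(ts)
    return 0.5 * period if period is not None else 0.3


def find_extrema(ts: TimeSeries, params: PeakParams | None = None,
                 which: str = "maxima") -> np.ndarray:
    """Times of gated local extrema of a channel.

    Candidates are interior local maxima (minima via negation); plateaus
    resolve to their earliest sample.  A candidate survives when its
    prominence reaches ``min_prominence`` x the channel's robust amplitude
    and no taller retained extremum lies within ``min_separation``
    (conflicts resolved tallest-first, ties toward the earlier sample).
    """
    if which not in ("maxima", "minima"):
        raise ValueError("which must be 'maxima' or 'minima'")
    params = params or PeakParams()
    if ts.n < 3:
        return np.empty(0)
    x = ts.values if which == "maxima" else -ts.values
    cand = _local_max_indices(x)
    if cand.size == 0:
        return np.empty(0)
    robust_amp = float(np.percentile(ts.values, 95) - np.percentile(ts.values, 5))
    if robust_amp > 0 and params.min_prominence > 0:
        prom = sps.peak_prominences(x, cand)[0]
        cand = cand[prom >= params.min_prominence * robust_amp - 1e-12]
    if cand.size == 0:
        return np.empty(0)
    min_sep_samples = _resolve_min_separation(ts, params) * ts.rate
    # greedy selection: tallest first, ties to the earlier sample
    order = np.lexsort((cand, -x[cand]))
    kept: list[int] = []
    for i in cand[order]:
        if all(abs(i - j) >= min_sep_samples - 1e-9 for j in kept):
            kept.append(i)
    kept_arr = np.sort(np.asarray(kept, dtype=int))
    return ts.t0 + kept_arr / ts.rate


def _warn_if_empty(times: np.ndarray, ts: TimeSeries, what: str) -> None:
    degenerate = ts.n < 3 or np.ptp(ts.values) == 0
    if times.size == 0 and not degenerate:
        warnings.warn(f"no {what} detected on a non-degenerate trace "
                      f"({ts.label or 'unnamed channel'})", DetectionWarning, stacklevel=3)


def _series(condition, ic_times, tc_times, side, source) -> EventSeries:
    events = [GaitEvent(float(t), "IC", side, source) for t in ic_times]
    events += [GaitEvent(float(t), "TC", side, source) for t in tc_times]
    return EventSeries(events, condition)


def detect_omc(displacement_ic: TimeSeries, displacement_tc: TimeSeries,
               condition: str, params: PeakParams | None = None,
               side: str = "L") -> EventSeries:
    """Kinematic detector on preprocessed foot-pelvis displacement traces.

    ``displacement_ic`` / ``displacement_tc`` are the traces used for initial
    and terminal contacts respectively (they may be the same trace).  Forward
    walking: IC at maxima of the first, TC at minima of the second; backward
    walking swaps the extrema labels.
    """
    if condition == "FW":
        ic = find_extrema(displacement_ic, params, "maxima")
        tc = find_extrema(displacement_tc, params, "minima")
    elif condition == "BW":
        ic = find_extrema(displacement_ic, params, "minima")
        tc = find_extrema(displacement_tc, params, "maxima")
    else:
        raise ValueError(f"condition must be FW or BW, got {condition!r}")
    _warn_if_empty(ic, displacement_ic, "initial contacts")
    _warn_if_empty(tc, displacement_tc, "terminal contacts")
    return _series(condition, ic, tc, side, "OMC")


def detect_imu_fw(h_acc_z: TimeSeries, h_gy_z: TimeSeries,
                  params: PeakParams | None = None, side: str = "L") -> EventSeries:
    """Forward-walking IMU detector on smoothed heel channels.

    IC at maxima of H.ACC.Z; TC at minima of H.GY.Z.  (The maxima/minima
    assignment to the two channels is the documented reading of an ambiguous
    rule; see the methods note.)
    """
    ic = find_extrema(h_acc_z, params, "maxima")
    tc = find_extrema(h_gy_z, params, "minima")
    _warn_if_empty(ic, h_acc_z, "initial contacts")
    _warn_if_empty(tc, h_gy_z, "terminal contacts")
    return _series("FW", ic, tc, side, "IMU")


def below_threshold_runs(ts: TimeSeries, threshold_sd: float = 1.0,
                         min_run: float = 0.010) -> list[tuple[int, int]]:
    """Maximal contiguous runs of samples below mean - threshold_sd * SD.

    SD is the sample standard deviation of the whole record.  Runs shorter
    than ``min_run`` seconds are discarded.  Returns (start, stop) index
    pairs, stop exclusive.
    """
    x = ts.values
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd == 0.0:
        raise ValueError("zero-variance channel: the SD threshold rule is undefined")
    theta = float(np.mean(x)) - threshold_sd * sd
    below = x < theta
    if not below.any():
        return []
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = list(edges[~below[edges]] + 1)
    stops = list(edges[below[edges]] + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        stops.append(x.size)
    min_count = min_run * ts.rate
    return [(a, b) for a, b in zip(starts, stops) if b - a >= min_count - 1e-9]


def _first_run_minimum(x: np.ndarray, start: int, stop: int) -> int:
    """First strict local minimum inside a run; global run minimum if none."""
    for i in range(max(start, 1), min(stop, x.size - 1)):
        if x[i] < x[i - 1] and x[i] < x[i + 1]:
            return i
    return start + int(np.argmin(x[start:stop]))  # monotone run: earliest minimum


def detect_imu_bw(t_acc_z: TimeSeries, params: PeakParams | None = None,
                  side: str = "L") -> EventSeries:
    """Backward-walking IMU detector on the preprocessed T.ACC.Z channel.

    IC at channel maxima.  TC: one event per below-threshold run (threshold
    mean - threshold_sd * SD over the whole record), placed at the first
    local minimum of the run.
    """
    params = params or PeakParams()
    ic = find_extrema(t_acc_z, params, "maxima")
    runs = below_threshold_runs(t_acc_z, params.threshold_sd, params.min_run)
    tc_idx = [_first_run_minimum(t_acc_z.values, a, b) for a, b in runs]
    tc = t_acc_z.t0 + np.asarray(tc_idx, dtype=float) / t_acc_z.rate
    _warn_if_empty(ic, t_acc_z, "initial contacts")
    if len(runs) == 0:
        warnings.warn("no below-threshold runs in T.ACC.Z: zero terminal contacts",
                      DetectionWarning, stacklevel=2)
    return _series("BW", ic, tc, side, "IMU")


# ---------------------------------------------------------------------------
# trial-level pipeline
# ---------------------------------------------------------------------------

def detect_trial(trial: Trial, method: str, params: PeakParams | None = None,
                 sides: Sequence[str] = ("L", "R"), zero_phase: bool = True,
                 heel_marker: str = "HEEL", toe_marker: str = "TOE",
                 pelvis_markers: Sequence[str] = DEFAULT_PELVIS_MARKERS,
                 head_trim_s: float = 1.0, tail_trim_s: float = 1.0) -> EventSeries:
    """Run one detector end-to-end on a trial: trim, filter, detect, merge sides.

    ``method`` is ``'omc'`` or ``'imu'``.  For the kinematic method, initial
    contact uses the heel marker and terminal contact the toe marker in
    forward walking (the anatomical point that strikes/leaves the ground),
    reversed for backward walking; pass ``toe_marker=heel_marker`` for a
    single-marker mode.
    """
    cond = trial.condition
    events: list[GaitEvent] = []
    for side in sides:
        if method == "omc":
            def disp(marker_base: str) -> TimeSeries:
                raw = relative_displacement(trial.markers, f"{marker_base}_{side}",
                                            pelvis_markers)
                return prep.kinematic_chain(trim_edges(raw, head_trim_s, tail_trim_s),
                                            zero_phase=zero_phase)
            if cond == "FW":
                series = detect_omc(disp(heel_marker), disp(toe_marker), cond, params, side)
            else:
                series = detect_omc(disp(toe_marker), disp(heel_marker), cond, params, side)
        elif method == "imu":
            if cond == "FW":
                acc = prep.accelerometer_chain(
                    trim_edges(trial.imu.get("H", "ACC", "Z", side), head_trim_s, tail_trim_s),
                    zero_phase=zero_phase)
                gy = prep.gyroscope_chain(
                    trim_edges(trial.imu.get("H", "GY", "Z", side), head_trim_s, tail_trim_s),
                    zero_phase=zero_phase)
                series = detect_imu_fw(prep.savgol(acc), prep.savgol(gy), params, side)
            else:
                acc = prep.accelerometer_chain(
                    trim_edges(trial.imu.get("T", "ACC", "Z", side), head_trim_s, tail_trim_s),
                    zero_phase=zero_phase)
                series = detect_imu_bw(acc, params, side)
        else:
            raise ValueError(f"method must be 'omc' or 'imu', got {method!r}")
        events.extend(series.events)
    merged = EventSeries(events, cond)
    for msg in merged.alternation_violations():
        warnings.warn(f"IC/TC alternation violation: {msg}", DetectionWarning, stacklevel=2)
    return merged
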