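"""Per-channel filter chain used ahead of event detection.

Kinematic (marker / displacement) channels: first-order low-pass Butterworth at
10 Hz followed by an order-3, 51-sample Savitzky-Golay smoother.  Accelerometer
channels: the same 10 Hz low-pass.  Gyroscope channels: first-order band-pass
Butterworth, 0.001-5 Hz.

All filters preserve length, rate and start time.  By default Butterworth
filters run zero-phase (forward-backward): causal filtering would add a
systematic lag to the IMU events and bias the between-method agreement
statistics, and the zero-phase pass leaves the peak of a symmetric pulse at
the pulse centre.  A causal mode is provided for sensitivity checks (note that
the forward-backward pass squares the magnitude response, so the familiar
-3 dB point at the cutoff applies to the single-pass mode only).  In causal
mode the filter state is initialised to the steady-state response to the first
sample, so a constant input immediately yields its steady-state output
(the constant for a low-pass, zero for a band-pass).

The band-pass low edge of 0.001 Hz at 1000 Hz is numerically delicate; filters
are therefore designed and applied as cascaded second-order sections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signals import TimeSeries

KINEMATIC_LOWPASS_HZ = 10.0
ACC_LOWPASS_HZ = 10.0
GYRO_BANDPASS_HZ = (0.001, 5.0)
BUTTER_ORDER = 1
SAVGOL_WINDOW = 51
SAVGOL_POLYORDER = 3


@dataclass(frozen=True)
class FilterSpec:
    """Declarative description of one filter stage (config-file friendly).

    ``cutoffs`` carries one Hz value (lowpass), two (bandpass), or
    ``(window_samples, polyorder)`` for the Savitzky-Golay kind.
    """

    kind: str  # 'lowpass' | 'bandpass' | 'savgol'
    order: int = BUTTER_ORDER
    cutoffs: tuple[float, ...] = (KINEMATIC_LOWPASS_HZ,)
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandpass", "savgol"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order <= 0:
            raise ValueError("filter order must be positive")
        if self.kind == "savgol":
            window, poly = int(self.cutoffs[0]), int(self.cutoffs[1])
            if window % 2 == 0 or window <= poly:
                raise ValueError("Savitzky-Golay window must be odd and exceed polyorder")

    def apply(self, ts: TimeSeries) -> TimeSeries:
        if self.kind == "savgol":
            return savgol(ts, int(self.cutoffs[0]), int(self.cutoffs[1]))
        return butterworth(ts, self.kind, self.cutoffs, self.order, self.zero_phase)


def _design_sos(kind: str, cutoffs, order: int, rate: float) -> np.ndarray:
    nyq = rate / 2.0
    cutoffs = tuple(float(c) for c in (cutoffs if np.iterable(cutoffs) else (cutoffs,)))
    if any(c <= 0 or c >= nyq for c in cutoffs):
        raise ValueError(f"cutoffs {cutoffs} must lie strictly inside (0, {nyq}) Hz")
    if kind == "lowpass":
        if len(cutoffs) != 1:
            raise ValueError("lowpass takes exactly one cutoff")
        return sps.butter(order, cutoffs[0], btype="lowpass", fs=rate, output="sos")
    if kind == "bandpass":
        if len(cutoffs) != 2 or cutoffs[0] >= cutoffs[1]:
            raise ValueError("bandpass takes (low, high) with low < high")
        return sps.butter(order, cutoffs, btype="bandpass", fs=rate, output="sos")
    raise ValueError(f"unknown Butterworth kind {kind!r}")


def butterworth(ts: TimeSeries, kind: str, cutoffs, order: int = BUTTER_ORDER,
                zero_phase: bool = True) -> TimeSeries:
    """Butterworth low-/band-pass; zero-phase (filtfilt) by default."""
    sos = _design_sos(kind, cutoffs, order, ts.rate)
    x = ts.values
    if zero_phase:
        # default padding needs ~6x the section count; guard tiny records
        padlen = min(3 * (2 * sos.shape[0] + 1), x.size - 1)
        if padlen < 1:
            raise ValueError("record too short for zero-phase filtering")
        y = sps.sosfiltfilt(sos, x, padlen=padlen)
    else:
        zi = sps.sosfilt_zi(sos) * x[0]
        y, _ = sps.sosfilt(sos, x, zi=zi)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite filter output")
    return ts.with_values(y)


def lowpass(ts: TimeSeries, cutoff_hz: float, order: int = BUTTER_ORDER,
            zero_phase: bool = True) -> TimeSeries:
    return butterworth(ts, "lowpass", (cutoff_hz,), order, zero_phase)


def bandpass(ts: TimeSeries, low_hz: float, high_hz: float, order: int = BUTTER_ORDER,
             zero_phase: bool = True) -> TimeSeries:
    return butterworth(ts, "bandpass", (low_hz, high_hz), order, zero_phase)


def savgol(ts: TimeSeries, window: int = SAVGOL_WINDOW,
           polyorder: int = SAVGOL_POLYORDER) -> TimeSeries:
    """Savitzky-Golay smoothing (exact on polynomials up to ``polyorder``)."""
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if window <= polyorder:
        raise ValueError("Savitzky-Golay window must exceed the polynomial order")
    if window > ts.n:
        raise ValueError(f"window of {window} samples exceeds record length {ts.n}")
    y = sps.savgol_filter(ts.values, window, polyorder, mode="interp")
    return ts.with_values(y)


# ---------------------------------------------------------------------------
# standard chains
# ---------------------------------------------------------------------------

def kinematic_chain(ts: TimeSeries, zero_phase: bool = True) -> TimeSeries:
    """Marker / displacement preprocessing: 10 Hz low-pass + SavGol(51, 3)."""
    return savgol(lowpass(ts, KINEMATIC_LOWPASS_HZ, zero_phase=zero_phase))


def accelerometer_chain(ts: TimeSeries, zero_phase: bool = True) -> TimeSeries:
    """Accelerometer preprocessing: 10 Hz first-order low-pass."""
    return lowpass(ts, ACC_LOWPASS_HZ, zero_phase=zero_phase)


def gyroscope_chain(ts: TimeSeries, zero_phase: bool = True) -> TimeSeries:
    """Gyroscope preprocessing: 0.001-5 Hz first-order band-pass."""
    return bandpass(ts, *GYRO_BANDPASS_HZ, zero_phase=zero_phase)
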