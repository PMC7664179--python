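"""Ground-truth treadmill gait simulator.

Generates one synthetic trial — marker trajectories at 100 Hz and IMU
channels at 1000 Hz on a shared trigger clock — together with the exact
initial-contact (IC) and terminal-contact (TC) times, for forward (FW) or
backward (BW) walking.

Generative model
----------------
Stride times are drawn from a normal distribution truncated at +/-3 SD;
cumulative sums give the IC times, and TC follows each IC by the stance
fraction (duty factor) of that stride.  The two sides carry independent
stride sequences offset by half a stride.

The foot-pelvis anterior-posterior displacement is ``A * cos(2*pi*phi(t))``
(sign flipped for BW), where the phase ``phi`` increases monotonically
through 0 at each IC and 0.5 at each TC.  Between events the phase is linear
(constant stance/swing rate — the belt drags the foot through stance and the
swing returns it); around each event the stance/swing rate change is blended
so that the local phase is "linear + even" in time about the event.  The
waveform curvature is then symmetric at every extremum up to third order,
which keeps the extrema of the *smoothed* trace on the truth events: a
polynomial-preserving smoother (Savitzky-Golay) or a wide-band zero-phase
low-pass does not displace such peaks, whereas a plain curvature jump at the
event (e.g. literal linear-drift stance meeting a raised-cosine swing) is
smeared into a systematic shift of tens of milliseconds.

The default duty factor is 0.5: the standard 51-sample (0.51 s at 100 Hz)
Savitzky-Golay window is wider than a full swing phase at normal cadence, so
with an asymmetric stance/swing split no monotone stance-swing morphology can
be locally symmetric about its extrema over the smoother's span, and the
kinematic events acquire a systematic shift that grows with the asymmetry
(about 20 ms at a stance fraction of 0.6).  That shift is a genuine property
of extremum-based detection on asymmetric waveforms, not a detector defect;
``duty_factor`` exposes it for sensitivity studies while the symmetric
default keeps ground-truth timing exact for validation.

IMU channels are built from symmetric raised-cosine transients tied to the
events: H.ACC.Z carries an impact complex at each IC (a contact bump plus a
decaying high-frequency ring); H.GY.Z is a smooth stride-periodic waveform
whose minimum falls at TC (with a mid-swing counter-swing lobe); T.ACC.Z
(used in BW) carries a positive transient at IC and a negative dip of depth
``dip_depth`` centred at TC that reliably crosses the mean - 1 SD threshold.
Independent Gaussian noise is added per channel.

Trial margins guarantee that trimming the first and last second leaves every
ground-truth event strictly inside the analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .signals import (CONDITIONS, EventSeries, GaitEvent, ImuRecord, MarkerSet,
                      TimeSeries, Trial)

#: the trimming convention the detectors apply (seconds dropped at each edge)
EDGE_TRIM_S = 1.0

PELVIS_BASE = {  # (AP, ML, vertical) base positions, metres
    "ASIS_L": (0.10, 0.13, 0.95),
    "ASIS_R": (0.10, -0.13, 0.95),
    "PSIS_L": (-0.10, 0.05, 0.97),
    "PSIS_R": (-0.10, -0.05, 0.97),
}
FOOT_ML = {"L": 0.10, "R": -0.10}
TOE_AP_OFFSET = 0.15   # toe marker sits ahead of the heel marker (m)


@dataclass
class SimConfig:
    """Parameters of one simulated trial.

    Defaults describe a comfortable-speed forward trial (speed 1.34 m/s);
    :func:`battery_configs` derives the slow/comfortable/fast FW and BW
    regimes.  Stride-time variability defaults to 15 ms (CV ~1.4%): fixed
    belt speed paces the gait, and treadmill stride-time variability in
    healthy adults is markedly lower than overground.
    """

    condition: str = "FW"
    n_strides: int = 50
    stride_time_mean: float = 1.08   # s
    stride_time_sd: float = 0.015    # s
    duty_factor: float = 0.50        # stance fraction of the stride
    speed: float = 1.34              # belt speed, m/s
    impact_amp: float = 1.5          # g, IC transient amplitude
    impact_decay: float = 0.02       # s, decay of the high-frequency ring
    impact_freq: float = 40.0        # Hz, ring frequency
    dip_depth: float = 1.5           # g, BW pre-TC dip depth
    dip_halfwidth: float = 0.04      # s, BW dip half-width
    gyro_amp: float = 250.0          # deg/s, TC lobe amplitude
    gyro_swing_amp: float = 150.0    # deg/s, mid-swing lobe amplitude
    noise_sd_marker: float = 0.001   # m
    noise_sd_acc: float = 0.02       # g
    noise_sd_gyro: float = 5.0       # deg/s
    marker_rate: float = 100.0       # Hz
    imu_rate: float = 1000.0         # Hz
    sides: tuple[str, ...] = ("L", "R")
    seed: int = 0
    speed_label: str = "comfortable"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.n_strides < 1:
            raise ValueError("n_strides must be at least 1")
        if not 0 < self.duty_factor < 1:
            raise ValueError("duty_factor must lie in (0, 1)")
        if self.stride_time_mean <= 3 * self.stride_time_sd:
            raise ValueError("stride_time_mean must exceed 3 x stride_time_sd")
        for name in ("stride_time_mean", "speed", "marker_rate", "imu_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("stride_time_sd", "impact_amp", "impact_decay", "dip_depth",
                     "noise_sd_marker", "noise_sd_acc", "noise_sd_gyro"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _stride_times(cfg: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    if cfg.stride_time_sd == 0:
        return np.full(size, cfg.stride_time_mean)
    return truncnorm.rvs(-3.0, 3.0, loc=cfg.stride_time_mean,
                         scale=cfg.stride_time_sd, size=size, random_state=rng)


def _event_phase(t: np.ndarray, knots: np.ndarray, cap_halfwidth: float,
                 cap_rate: float) -> np.ndarray:
    """Monotone phase hitting k/2 exactly at the k-th event knot.

    Every interior knot wears an identical linear "cap": within
    ``|t - knot| <= cap_halfwidth`` the phase is exactly
    ``knot_value + cap_rate * (t - knot)``, so ``cos(2*pi*phase)`` has the
    same, time-symmetric shape around every extremum regardless of
    stride-to-stride timing jitter — a symmetric smoother then cannot
    displace the extrema.  The length variation of individual stance/swing
    segments is absorbed by C1 connectors between caps whose slope profile
    ``cap_rate + 6*delta*tau*(1-tau)`` matches the cap slope at both seams
    and integrates to the required half-cycle phase advance.
    """
    m = knots.size
    vals = 0.5 * np.arange(m)
    phi = np.interp(t, knots, vals)  # clamped endpoints; interior overwritten
    w = cap_halfwidth
    r = cap_rate
    for j in range(m - 1):
        a, b = knots[j], knots[j + 1]
        wa = w if j > 0 else 0.0           # edge segments: no cap outside
        wb = w if j + 1 < m - 1 else 0.0
        lc = (b - wb) - (a + wa)
        if lc <= 0:
            raise ValueError("phase caps overlap: segment shorter than caps")
        delta = (0.5 - r * (wa + wb)) / lc - r
        i0 = np.searchsorted(t, a)
        i1 = np.searchsorted(t, b)
        u = t[i0:i1] - a
        seg_phi = np.empty_like(u)
        in_a = u < wa
        in_b = u > (b - a) - wb
        mid = ~in_a & ~in_b
        seg_phi[in_a] = r * u[in_a]
        if r + 1.5 * delta <= 0:
            raise ValueError("phase connector not monotone: segment lengths too "
                             "uneven for the cap rate")
        tau = (u[mid] - wa) / lc
        seg_phi[mid] = r * wa + lc * (r * tau + 6.0 * delta * (tau ** 2 / 2 - tau ** 3 / 3))
        seg_phi[in_b] = 0.5 - r * ((b - a) - u[in_b])
        phi[i0:i1] = vals[j] + seg_phi
    return phi


def _cap_halfwidth(duty: float, stride_time_mean: float, stride_time_sd: float) -> float:
    """Half-width of the symmetric phase caps around each displacement extremum.

    As wide as the shortest realizable stance/swing segment allows (two caps
    plus a connector must fit in every segment), so the caps cover as much of
    a smoothing kernel's span as the morphology permits.
    """
    min_seg = min(duty, 1 - duty) * (stride_time_mean - 3 * stride_time_sd)
    return max(0.5 * min_seg - 0.02, 0.3 * min_seg)


def _bump(t: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Raised-cosine bump, unit height, support [center - hw, center + hw]."""
    u = t - center
    out = np.zeros_like(t)
    m = np.abs(u) < halfwidth
    out[m] = 0.5 * (1.0 + np.cos(np.pi * u[m] / halfwidth))
    return out


def _add_bump(x: np.ndarray, t: np.ndarray, rate: float, center: float,
              halfwidth: float, amp: float) -> None:
    i0 = max(0, int(np.floor((center - halfwidth - t[0]) * rate)))
    i1 = min(t.size, int(np.ceil((center + halfwidth - t[0]) * rate)) + 1)
    if i1 > i0:
        x[i0:i1] += amp * _bump(t[i0:i1], center, halfwidth)


def _add_ring(x: np.ndarray, t: np.ndarray, rate: float, start: float,
              amp: float, decay: float, freq: float) -> None:
    stop = start + 6.0 * decay
    i0 = max(0, int(np.ceil((start - t[0]) * rate)))
    i1 = min(t.size, int(np.ceil((stop - t[0]) * rate)) + 1)
    if i1 > i0:
        u = t[i0:i1] - start
        x[i0:i1] += amp * np.exp(-u / decay) * np.sin(2 * np.pi * freq * u)


def simulate_trial(config: SimConfig) -> tuple[Trial, EventSeries]:
    """Build one synthetic trial and its ground-truth events.

    Deterministic given ``config.seed``.  The ground truth contains every
    IC/TC falling strictly inside the trimmed analysis window
    ``(EDGE_TRIM_S, duration - EDGE_TRIM_S)``; with two antiphase sides the
    per-side event counts are ``n_strides`` or ``n_strides + 1``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_strides
    tm = cfg.stride_time_mean
    duty = cfg.duty_factor

    # per-side event grids, two virtual straddling strides (index 0 and n+1)
    ic_all: dict[str, np.ndarray] = {}
    tc_all: dict[str, np.ndarray] = {}
    for s_i, side in enumerate(cfg.sides):
        T = _stride_times(cfg, rng, n + 2)
        ic = np.empty(n + 2)
        tc = np.empty(n + 2)
        tc[0] = EDGE_TRIM_S - 0.15 * tm + s_i * tm / 2.0
        ic[0] = tc[0] - duty * T[0]
        for k in range(1, n + 2):
            ic[k] = ic[k - 1] + T[k - 1]
            tc[k] = ic[k] + duty * T[k]
        ic_all[side], tc_all[side] = ic, tc

    # End the analysis window inside a clear gap of the combined event
    # sequence: every in-window event then keeps enough post-event signal for
    # its extremum to carry full prominence and to sit clear of the
    # Savitzky-Golay edge-fit zone (~0.26 s), while every excluded event's
    # extremum falls beyond the trimmed record (no spurious edge peaks).
    all_ev = np.sort(np.concatenate(list(ic_all.values()) + list(tc_all.values())))
    m_floor = 0.30                      # s, edge-zone + prominence clearance
    m_target = max(0.35 * tm, m_floor + 0.01)
    # never include a side's terminal phase knot: beyond it the displacement
    # clamps flat, so that event would have no right flank to detect
    cap = min(tc[n + 1] for tc in tc_all.values()) - 0.02
    target = max(tc[n] for tc in tc_all.values())
    candidates = all_ev[(all_ev < cap) & (all_ev <= target + 1e-12)]
    window_end = None
    for i in range(candidates.size - 1, -1, -1):
        k = int(np.searchsorted(all_ev, candidates[i], side="right"))
        nxt = all_ev[k] if k < all_ev.size else np.inf
        room = min(nxt - 0.05, cap) - candidates[i]
        if room >= m_floor:
            window_end = candidates[i] + min(m_target, room)
            break
    if window_end is None:
        window_end = cap
    duration = np.ceil((window_end + EDGE_TRIM_S) * cfg.marker_rate) / cfg.marker_rate

    t_m = np.arange(int(round(duration * cfg.marker_rate))) / cfg.marker_rate
    t_i = np.arange(int(round(duration * cfg.imu_rate))) / cfg.imu_rate

    # phase-anchored foot-pelvis displacement per side
    amp_disp = cfg.speed * duty * tm / 2.0
    sign = 1.0 if cfg.condition == "FW" else -1.0
    cap_halfwidth = _cap_halfwidth(duty, tm, cfg.stride_time_sd)
    disp = {}
    for side in cfg.sides:
        knots = np.empty(2 * (n + 2))
        knots[0::2] = ic_all[side]
        knots[1::2] = tc_all[side]
        phi = _event_phase(t_m, knots, cap_halfwidth, 1.0 / tm)
        disp[side] = sign * amp_disp * np.cos(2 * np.pi * phi)

    # markers: pelvis cluster with small AP sway, feet riding the displacement
    sway = 0.01 * np.sin(2 * np.pi * t_m / tm + rng.uniform(0, 2 * np.pi))
    markers: dict[str, dict[str, TimeSeries]] = {}

    def put(name: str, x: np.ndarray, y: float, z: float) -> None:
        axes = {}
        for axis, base in (("X", x), ("Y", np.full_like(t_m, y)),
                           ("Z", np.full_like(t_m, z))):
            noisy = base + rng.normal(0.0, cfg.noise_sd_marker, t_m.size)
            axes[axis] = TimeSeries(noisy, cfg.marker_rate, 0.0, f"{name}.{axis}")
        markers[name] = axes

    for name, (ap, ml, vert) in PELVIS_BASE.items():
        put(name, ap + sway, ml, vert)
    for side in cfg.sides:
        put(f"HEEL_{side}", sway + disp[side] - TOE_AP_OFFSET / 2, FOOT_ML[side], 0.05)
        put(f"TOE_{side}", sway + disp[side] + TOE_AP_OFFSET / 2, FOOT_ML[side], 0.03)

    # IMU channels; contact-transient widths scale with cadence so slow
    # strides keep the same waveform-to-record amplitude structure
    w_gy = 0.10 * tm            # TC lobe half-width
    w_gy_swing = 0.12 * tm      # mid-swing lobe half-width
    w_scale = max(1.0, tm / 1.08)
    w_contact = 0.05 * w_scale  # IC contact-bump half-width
    w_dip = cfg.dip_halfwidth * w_scale
    channels: dict[str, TimeSeries] = {}
    for side in cfg.sides:
        ic, tc = ic_all[side], tc_all[side]

        h_acc = np.full(t_i.size, 1.0)
        for c in ic:
            _add_bump(h_acc, t_i, cfg.imu_rate, c, w_contact, cfg.impact_amp)
            _add_ring(h_acc, t_i, cfg.imu_rate, c, 0.5 * cfg.impact_amp,
                      cfg.impact_decay, cfg.impact_freq)
        h_acc += rng.normal(0.0, cfg.noise_sd_acc, t_i.size)

        h_gy = np.zeros(t_i.size)
        for k in range(len(tc)):
            _add_bump(h_gy, t_i, cfg.imu_rate, tc[k], w_gy, -cfg.gyro_amp)
            if k + 1 < len(ic):   # mid-swing counter lobe, clear of the TC lobe
                center = tc[k] + 0.55 * (ic[k + 1] - tc[k])
                _add_bump(h_gy, t_i, cfg.imu_rate, center, w_gy_swing,
                          cfg.gyro_swing_amp)
        h_gy += rng.normal(0.0, cfg.noise_sd_gyro, t_i.size)

        t_acc = np.full(t_i.size, 1.0)
        for c in ic:
            _add_bump(t_acc, t_i, cfg.imu_rate, c, w_contact, cfg.impact_amp)
        for c in tc:
            _add_bump(t_acc, t_i, cfg.imu_rate, c, w_dip, -cfg.dip_depth)
        t_acc += rng.normal(0.0, cfg.noise_sd_acc, t_i.size)

        for key, arr in ((f"H.ACC.Z.{side}", h_acc), (f"H.GY.Z.{side}", h_gy),
                         (f"T.ACC.Z.{side}", t_acc)):
            channels[key] = TimeSeries(arr, cfg.imu_rate, 0.0, key)

    # ground truth: all events strictly inside the trimmed analysis window
    lo, hi = EDGE_TRIM_S, duration - EDGE_TRIM_S
    events = []
    for side in cfg.sides:
        for t in ic_all[side]:
            if lo < t < hi:
                events.append(GaitEvent(float(t), "IC", side, "TRUTH"))
        for t in tc_all[side]:
            if lo < t < hi:
                events.append(GaitEvent(float(t), "TC", side, "TRUTH"))
    truth = EventSeries(events, cfg.condition)

    trial = Trial(
        MarkerSet(markers, walking_axis="X", forward_sign=1),
        ImuRecord(channels),
        cfg.condition,
        metadata={"seed": cfg.seed, "speed": cfg.speed, "n_strides": cfg.n_strides,
                  "speed_label": cfg.speed_label, "duration_s": float(duration),
                  "stride_time_mean": cfg.stride_time_mean,
                  "stride_time_sd": cfg.stride_time_sd},
    )
    return trial, truth


# ---------------------------------------------------------------------------
# study-regime battery
# ---------------------------------------------------------------------------

#: mean +/- SD treadmill speeds (m/s) for the two conditions
FW_SPEEDS = {"slow": 1.12, "comfortable": 1.34, "fast": 1.56}
BW_SPEEDS = {"slow": 0.42, "comfortable": 0.54, "fast": 0.66}
#: nominal stride lengths (m) used to map belt speed to stride time
STRIDE_LENGTH = {"FW": 1.45, "BW": 0.80}
#: full-scale strides per side per trial: 258 x 2 sides x 3 speeds ~= 1550 FW
#: initial contacts, 220 x 2 x 3 ~= 1320 BW initial contacts
FULL_SCALE_STRIDES = {"FW": 258, "BW": 220}


def battery_configs(scale: float = 1.0, seed: int = 0) -> list[SimConfig]:
    """Six trial configs: FW and BW at slow/comfortable/fast belt speeds.

    ``scale`` multiplies the stride counts (scale=0.1 gives ~26/22 strides
    per side, about a 30 s recording per trial).  Seeds for the individual
    trials are spawned deterministically from ``seed``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(6)
    configs = []
    i = 0
    for condition, speeds in (("FW", FW_SPEEDS), ("BW", BW_SPEEDS)):
        for label, speed in speeds.items():
            stride_time = STRIDE_LENGTH[condition] / speed
            configs.append(SimConfig(
                condition=condition,
                n_strides=max(3, int(round(FULL_SCALE_STRIDES[condition] * scale))),
                stride_time_mean=stride_time,
                speed=speed,
                speed_label=label,
                seed=int(children[i].generate_state(1)[0] % (2 ** 31)),
            ))
            i += 1
    return configs
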