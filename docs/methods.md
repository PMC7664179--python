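# Methods

This note documents the models, rules, parameters and numerical choices
behind `gaitmark`: the two gait-event detection routes, the agreement
statistics, and the synthetic-trial generator used to validate them.

## Data model

A trial couples two uniformly sampled streams on one hardware-trigger clock
(t = 0 at the trigger): marker trajectories (meters, 100 Hz) and IMU
channels (accelerometer in g, gyroscope in deg/s, 1000 Hz). Sample *k* of a
channel carries the timestamp `t0 + k/rate`; detected event times are the
timestamps of identified samples, so kinematic events are quantized to 10 ms
and IMU events to 1 ms. The two streams are never resampled onto a common
grid — all between-method comparisons happen on event times in seconds.
Units are declared in the trial config, never inferred.

The first and last second of every record are discarded before processing
(`trim_edges`, defaults 1 s + 1 s), reflecting the standard practice of
dropping the unsteady edges of a 30 s treadmill recording.

## Preprocessing

| channel class | chain |
|---|---|
| marker / displacement | 1st-order Butterworth low-pass, 10 Hz → Savitzky–Golay, order 3, window 51 samples |
| accelerometer | 1st-order Butterworth low-pass, 10 Hz |
| gyroscope | 1st-order Butterworth band-pass, 0.001–5 Hz |

Butterworth filters run **zero-phase** (forward–backward) by default.
Whether the original processing chain was causal or zero-phase is not
determinable from its description; causal filtering would add a systematic,
cutoff-dependent lag to whichever channel it touches and therefore bias the
between-method agreement statistics, so zero-phase is the default and a
causal mode (`zero_phase=False`) is provided for sensitivity analyses. The
forward–backward pass squares the magnitude response; the familiar −3 dB
point at the cutoff applies to the single-pass (causal) mode. In causal
mode the filter state is initialized to the steady-state response to the
first sample, so a constant input immediately produces its steady-state
output. All filters are designed and applied as cascaded second-order
sections; the 0.001 Hz band-pass edge at 1000 Hz is numerically delicate
and the implementation guarantees finite output and a DC gain below 1e−3 on
a 30 s constant input.

The Savitzky–Golay smoothing applied to the forward-walking IMU channels
reuses the 51-sample window documented for the kinematic chain (the window
for that step is otherwise unspecified); it is configurable.

## Event detection

All four detectors share one peak engine, `find_extrema`: candidates are
interior local extrema (a plateau resolves to its earliest sample), gated by
topographic prominence (≥ `min_prominence` × the channel's 5th–95th
percentile range, default 0.1) and by a minimum separation (default: half
the dominant stride period, estimated from the channel autocorrelation
between 0.4 and 4 s lag). Conflicts under the separation gate are resolved
tallest-first with ties to the earlier sample. The autocorrelation default
suppresses noise extrema at the slowest backward speeds without merging
strides at the fastest forward speeds; both gates are overridable
(`PeakParams`).

* **Kinematic (both directions).** Foot AP displacement relative to the
  pelvis: `forward_sign × (foot_AP − centroid(pelvis_AP))`, with the pelvis
  reference the centroid of the four iliac-spine markers (left/right ASIS
  and PSIS) — a deliberate simplification of a full 6-DOF pelvis segment
  model, which is out of scope. Forward: IC at maxima, TC at minima;
  backward: labels swapped. Initial contact uses the heel marker and
  terminal contact the toe marker in forward walking (the anatomical point
  that strikes/leaves the ground first), reversed for backward walking;
  marker choice is configurable and passing the same marker twice gives a
  single-marker mode.
* **IMU forward.** IC at maxima of smoothed `H.ACC.Z`; TC at minima of
  smoothed `H.GY.Z`. The published sentence describing this rule is
  ambiguous about whether both channels contribute maxima; this package
  reads it as one event kind per channel (heel-accelerometer maxima → IC,
  heel-gyroscope minima → TC), which is the only reading that yields one IC
  and one TC per stride.
* **IMU backward.** IC at maxima of `T.ACC.Z`. TC: threshold
  θ = mean − `threshold_sd` × SD over the whole trimmed, filtered record
  (SD multiplier default 1.0); maximal contiguous runs of samples below θ
  lasting at least `min_run` (default 10 ms, rejecting single-sample noise
  excursions) each contribute exactly one TC at the run's first strict local
  minimum (the run's earliest global minimum sample if it is monotone).
  Using mean − 1 SD rather than a raw −1 SD value makes the rule invariant
  to constant offsets such as gravity; the SD is computed per trial, whole
  trimmed record.

Empty detections on non-degenerate traces raise a `DetectionWarning`, never
an exception, and IC/TC alternation violations are reported per stream —
never silently repaired.

## Agreement analysis

Events from two methods are paired one-to-one per event kind and side:
candidates within the matching tolerance (default 100 ms — above the widest
limits-of-agreement magnitude such detectors produce, so genuine pairs are
never dropped) are accepted greedily by increasing |Δt|, ties to the earlier
test event, subject to the pairing never crossing. Unpaired events are
tallied: a redundant detection appears as an unmatched test event, an
omission as an unmatched reference event, and neither contaminates the pair
statistics.

* **Mean absolute difference**: mean ± sample SD of |Δt| in ms.
* **Bland–Altman**: bias = mean Δt; 95 % limits of agreement =
  bias ± 1.96 × sample SD. Strides are treated as independent (no
  repeated-measures correction), matching the plain Bland–Altman plot.
  The sign convention is Δt = t_test − t_ref (with the kinematic method as
  reference: positive = IMU late); it is fixed here because published plots
  rarely state it.
* **Stride-time ICC**: stride times are successive differences of same-kind,
  same-side event times; between methods, only intervals whose two endpoint
  events are consecutively matched in both streams are paired, so a missed
  or extra event cannot silently fuse two strides. The ICC is ICC(2,1) —
  two-way random effects, absolute agreement, single measurement — the
  standard choice when two methods measure the same physical quantity,
  because it penalizes a constant offset; a consistency form is available
  (`form="consistency"`). The 95 % CI uses the variance-component
  F-quantile formulas (Satterthwaite degrees of freedom). Classification:
  poor < 0.5, moderate 0.5–0.75, good 0.75–0.9, excellent > 0.9, boundary
  values falling to the lower band as printed. Degenerate inputs (n < 3,
  numerically zero total variance) raise; sums of squares are computed
  directly (not by subtraction) so identical series return exactly 1.0.
* **Mann–Whitney U**: exact two-sided p by full enumeration of group
  assignments when min(n₁, n₂) ≤ 8 and n₁·n₂ ≤ 64 (midranks make the
  enumeration tie-correct by construction); tie-corrected normal
  approximation with continuity correction otherwise. No multiple-testing
  correction is applied, matching standard reporting of two comparisons.

Left and right sides are pooled by default and separable by flag; whether
sides should be pooled in such analyses is typically unstated in reports,
so both options exist.

## Synthetic gait generator

The generator produces a marker + IMU trial and its exact event times, for
validation. The generative model:

1. **Stride times** T_k ~ Normal(`stride_time_mean`, `stride_time_sd`)
   truncated at ±3 SD; cumulative sums give per-side IC times and
   TC_k = IC_k + `duty_factor` × T_k. The two sides carry independent
   sequences offset by half a stride. Truncated-normal stride times (rather
   than a phase oscillator) keep ground-truth timing statistics analytic.
2. **Foot–pelvis displacement** = A·cos(2π φ(t)) (sign flipped for backward
   walking), A = speed × duty × T̄ / 2. The phase φ rises monotonically
   through 0 at each IC and ½ at each TC. Around every event φ is exactly
   linear with the same slope 1/T̄ over a fixed cap (as wide as the shortest
   stance/swing segment allows), and C¹ connectors between caps absorb the
   per-stride timing jitter. Every displacement extremum therefore has an
   identical, time-symmetric neighborhood, which a zero-phase filter or a
   polynomial-preserving smoother cannot displace — the raw and low-passed
   extrema recover the truth events exactly, and only the Savitzky–Golay
   window's outer reach into the jitter-dependent connectors contributes a
   residual (≤ ~5 ms at the default jitter).
3. **Heel accelerometer** (`H.ACC.Z`): baseline 1 g plus, at each IC, a
   raised-cosine contact bump (amplitude `impact_amp`, default 1.5 g) and a
   decaying 40 Hz ring (`impact_decay` 20 ms) — the ring is mostly removed
   by the 10 Hz low-pass, as in real processing.
4. **Heel gyroscope** (`H.GY.Z`): a stride-periodic waveform whose minimum
   falls exactly at TC (negative lobe, `gyro_amp` 250 deg/s) with a
   mid-swing counter-rotation lobe placed clear of the TC lobe.
5. **Toe accelerometer** (`T.ACC.Z`, backward walking): baseline plus a
   positive IC bump and a negative raised-cosine dip of depth `dip_depth`
   (1.5 g) centered at TC. Centering the dip keeps its filtered minimum on
   the truth event (an asymmetric dip would shift it); the dip reliably
   crosses the mean − 1 SD threshold every stride, and its below-threshold
   run always exceeds the 10 ms minimum-run gate. Transient widths scale
   with stride time so slow trials keep the same amplitude structure.
6. **Noise**: independent Gaussian noise per channel — 1 mm marker noise,
   0.02 g accelerometer noise (typical foot-mounted MEMS RMS levels),
   5 deg/s gyroscope noise.
7. **Margins and ground truth.** Trials carry enough lead-in/out that the
   1 s edge trims never touch a stride. The analysis window ends inside a
   clear gap of the combined two-side event sequence, ≥ 0.3 s after the
   last included event (clearing the Savitzky–Golay edge-fit zone and
   preserving full peak prominence) and before the next excluded one; a
   side's terminal phase knot is never included (beyond it the displacement
   has no return flank). Ground truth is every event strictly inside the
   trimmed window: exactly `n_strides` ICs and TCs for a single-side trial;
   with two antiphase sides one side contributes one extra straddling
   event, so per-side counts are `n_strides` or `n_strides + 1`.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| `duty_factor` | 0.5 | The 51-sample smoother's half-span (0.26 s) exceeds half a swing phase at normal cadence, so for any asymmetric stance/swing split no monotone displacement morphology can be symmetric about its extrema over the smoother's span — the smoothed extrema then shift systematically (~20 ms at duty 0.6). That shift is a real property of extremum-based detection on asymmetric waveforms, not a detector defect; the symmetric default keeps ground-truth timing exact for validation, and `duty_factor` exposes the phenomenon for sensitivity studies. |
| `stride_time_sd` | 0.015 s | CV ≈ 1.4 %: fixed belt speed paces the gait, and treadmill stride-time variability in healthy adults is well below overground values. Jitter also leaks asymmetry into the smoother's outer band (~0.3 ms of event shift per ms of stride-time SD), which the default keeps within the kinematic sampling resolution. |
| `speed` / stride time | 1.34 m/s FW, 0.54 m/s BW | comfortable treadmill speeds for the two directions; stride times via nominal stride lengths 1.45 m (FW) / 0.80 m (BW). |
| noise SDs | 1 mm / 0.02 g / 5 deg/s | typical optical-capture and foot-mounted MEMS sensor noise. |

`battery_configs` builds the six-trial regime — forward and backward at
slow/comfortable/fast speeds (mean ± SD: 1.12/1.34/1.56 and
0.42/0.54/0.66 m/s) — with full-scale stride counts chosen so the battery
totals ≈ 1550 forward and ≈ 1320 backward initial contacts across both
feet; `scale` shrinks the counts proportionally (0.1 ≈ one 30 s recording
per trial, the size used by the test suite and the acceptance script, which
keeps the full battery under a few seconds of compute).

### What the simulator does and does not emulate

It reproduces the signal structure the detectors rely on: quasi-periodic
foot–pelvis displacement with extrema at the events, impact transients at
initial contact, swing-phase gyroscope lobes, the pre-terminal-contact
deceleration dip, stride-time variability, and sensor noise. It does **not**
model soft-tissue artifact, sensor-mount resonance, drift or bias
instability, double-support force sharing, pathological morphologies,
overground (non-treadmill) progression, or between-subject variability
(batteries of configs stand in for subjects). Passing validation here
demonstrates that the algorithms are implemented correctly and behave as
designed under the stated signal model — not that real recordings will show
the same (much smaller) errors: on synthetic trials the between-method
disagreement is dominated by the 10 ms kinematic sampling grid.

## Numerical choices and degenerate inputs

* Plateaus in extrema detection resolve to the earliest sample; equal-height
  conflicts under the separation gate keep the earlier peak.
* `find_extrema` on fewer than 3 samples, or on a channel whose robust
  amplitude is zero, returns an empty result (a constant trace has no
  extrema); the backward TC rule on a zero-variance channel raises, because
  its SD threshold is undefined.
* Matching tolerance ties break toward the earlier test event; the pairing
  is order-preserving by construction.
* Bland–Altman needs ≥ 2 pairs, the ICC ≥ 3 stride pairs; below that the
  report carries the counts and leaves the statistic empty rather than
  extrapolating.
* Zero-phase filtering of short records caps the filtfilt padding at the
  record length; records shorter than one pad length are rejected.
* Battery runs derive per-trial seeds from the master seed via
  `SeedSequence.spawn`, and summaries serialize with sorted keys, so a seed
  reproduces every artifact byte for byte.

## Known limitations

* The kinematic route inherits the 100 Hz sampling grid: a 10 ms resolution
  floor that dominates synthetic-data disagreement.
* ICC confidence intervals assume balanced, complete pairs; strides with an
  unmatched endpoint are dropped, not imputed.
* The exact Mann–Whitney mode enumerates up to C(16, 8) assignments; larger
  samples switch to the tie-corrected normal approximation.
* Single-subject trials only; between-subject variance enters only through
  config batteries.
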