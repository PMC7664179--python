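# gaitmark

Gait-event detection for **forward and backward treadmill walking**, from
optical motion-capture (OMC) kinematics and foot-mounted inertial sensors
(IMU), with the full between-method agreement analysis used in method
comparison studies — plus a ground-truth gait simulator to validate the whole
chain.

Backward walking is increasingly used in neurologic and orthopedic
rehabilitation, but gait analysis needs reliable timing of two events per
stride: **initial contact** (IC — heel strike going forward, toe strike going
backward) and **terminal contact** (TC — toe-off forward, heel-off backward).
This package implements and compares two indirect detection routes:

* **Kinematic**: the anterior-posterior displacement of a foot marker
  relative to the pelvis (Zeni-style). Forward walking: relative maxima are
  IC and relative minima are TC; backward walking swaps the labels.
* **IMU, forward**: maxima of the smoothed vertical heel-accelerometer
  channel (`H.ACC.Z`) are IC; minima of the smoothed heel gyroscope channel
  (`H.GY.Z`) are TC.
* **IMU, backward**: maxima of the vertical toe-accelerometer channel
  (`T.ACC.Z`) are IC; TC is the first local minimum of each contiguous run of
  samples below *mean − 1 SD* of the channel.

Channels are preprocessed with the standard chain (first-order zero-phase
Butterworth low-pass at 10 Hz for kinematics and accelerometers, 0.001–5 Hz
band-pass for gyroscopes, order-3/51-sample Savitzky–Golay smoothing where
the detector calls for it), and the first and last second of each record are
discarded.

Agreement between methods is quantified the way the field reports it:

* mean absolute difference of paired event times (ms),
* Bland–Altman bias and 95 % limits of agreement (bias ± 1.96 SD),
* intraclass correlation of stride times — ICC(2,1), two-way random effects,
  absolute agreement, single measurement — with F-based 95 % CI and the
  conventional bands (poor < 0.5 ≤ moderate ≤ 0.75 < good ≤ 0.9 < excellent),
* Mann–Whitney U comparison of absolute differences between conditions
  (exact enumeration for small samples, tie-corrected normal otherwise).

No marker/IMU dataset is bundled; the `simulate` module generates synthetic
treadmill trials with exactly known event times, so every detector and every
statistic can be validated end-to-end (see `docs/methods.md` for what the
simulator does and does not emulate).

## Worked example

```python
from gaitmark import SimConfig, simulate_trial, detect_trial, agreement_report

# one 30 s comfortable-speed forward trial, both feet, realistic sensor noise
trial, truth = simulate_trial(SimConfig(condition="FW", n_strides=26, seed=1))

omc = detect_trial(trial, "omc")   # kinematic method
imu = detect_trial(trial, "imu")   # inertial method

for kind, r in agreement_report(omc, imu).items():
    print(f"{kind}: n={r.n}  MAD={r.mad_ms:.2f}±{r.mad_sd_ms:.2f} ms  "
          f"bias={r.bias_ms:.2f} ms  LoA=({r.loa_low_ms:.2f}, {r.loa_high_ms:.2f}) ms  "
          f"ICC={r.icc:.3f} ({r.icc_class})")
```

prints

```
IC: n=53  MAD=2.47±1.46 ms  bias=0.28 ms  LoA=(-5.36, 5.92) ms  ICC=0.953 (excellent)
TC: n=53  MAD=3.08±1.49 ms  bias=-0.17 ms  LoA=(-6.91, 6.57) ms  ICC=0.866 (good)
```

Reading: across 53 paired initial contacts the two methods disagree by
2.5 ms on average, the IMU method is essentially unbiased (+0.28 ms), and
95 % of disagreements fall within about ±6 ms. On synthetic data the
disagreement is dominated by the 10 ms kinematic sampling grid; real
recordings add soft-tissue and sensor effects, so field numbers are larger.
The stride-time ICC of a single fixed-speed trial is capped by the small
true stride-time variance relative to that grid error (hence "good" for TC
here); pooling trials across belt speeds, as the replica battery does,
raises the between-stride variance and the ICC into the excellent band.

The same pipeline is scriptable from the shell:

```bash
gaitmark simulate --condition fw --n-strides 26 --seed 1 --out-dir trial/
gaitmark detect --condition fw --method omc --markers trial/markers.csv \
    --imu trial/imu.csv --out trial/events_omc.csv
gaitmark detect --condition fw --method imu --markers trial/markers.csv \
    --imu trial/imu.csv --out trial/events_imu.csv
gaitmark agree --ref trial/events_omc.csv --test trial/events_imu.csv \
    --out trial/report.json
gaitmark battery --seed 1 --out-dir battery/     # full FW+BW, 3 speeds each
```

Short narrative scripts for each capability live in `examples/`.

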