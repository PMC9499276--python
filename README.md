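# kneestab

Wearable-sensor assessment of knee stability, from raw signals to
test-retest reliability statistics.

After anterior-cruciate-ligament (ACL) reconstruction, clearance to return
to sport needs objective, *reliable* measures of knee stability during
sport-like movements. A practical field protocol instruments an athlete
with two magneto-inertial measurement units (MIMUs: tri-axial
accelerometer ±16 g, gyroscope ±2000 °/s, magnetometer ±4800 µT, 500 Hz)
on the tibia and foot dorsum, plus force plates (1000 Hz) for a
countermovement-jump (CMJ) baseline, and extracts stability parameters
from a single leg squat (SLS) and a crossover hop test (CHT). `kneestab`
implements that pipeline end to end:

* **preprocessing** — gyroscope static-bias removal and a quaternion
  complementary filter (gravity gain k₁ = 2.33 s⁻¹, heading gain
  k₂ = 7.44 s⁻¹) yielding the tibia pitch angle and gravity-aligned
  acceleration;
* **segmentation** — SLS onset/peak-flexion/end from a moving-SD threshold
  on the pitch (σ > 2·σ_static), CHT take-offs (d|ω|/dt < −0.6 rad/s²) and
  landings (first |a|-jerk peak > 7 m/s³) with a 100 ms post-landing risk
  window t_risk, CMJ unweighting-end (first GRF inflection) and flight
  start (GRFv ≈ 0);
* **features** — per-trial parameters: phase durations (T_tot, FT, CT),
  RMS and peak of the acceleration/angular-velocity magnitudes, sway path
  SP, 90% prediction-ellipse sway area SA and its eccentricity
  SAecc = √(1 − b²/a²), CMJ F_max and mass-normalised net impulse AUC_F;
* **reliability** — absolute-agreement two-way ICC with exact 95% CI and
  p-value, SEM = SD·√(1−ICC), MDC = SEM·1.96·√2, limb symmetry index
  LSI = non-dominant/dominant·100 (physiological band 85–115%), and the
  Walter–Eliasziw–Donner sample-size formula for planning reliability
  studies;
* **synthetic data** — a generator producing physiologically shaped IMU and
  force signals with known ground-truth events and variance components, so
  every stage is testable without recorded data.

## Worked example

Simulate a crossover-hop trial, segment it, and extract the second-hop
parameters:

```python
import numpy as np
from kneestab import (SimConfig, simulate_cht, remove_gyro_bias,
                      segment_cht, extract_cht_features,
                      icc_absolute_agreement, lsi, sample_size_reliability)

cfg = SimConfig(seed=0)
foot, tibia, gt = simulate_cht(cfg, seed=0)
foot = remove_gyro_bias(foot, (0, 1000))
tibia = remove_gyro_bias(tibia, (0, 1000))
ev = segment_cht(foot)
rec = extract_cht_features(foot, tibia, None, ev)
print([round(i / foot.fs, 3) for i in ev.to], [round(i / foot.fs, 3) for i in ev.la])
for k in ("FT", "CT", "T_tot", "RMSa_foot", "RMSw_foot", "wpeak_foot"):
    print(f"{k:>10}: {rec.values[k]:.3f}")
```

```
[2.994, 3.694, 4.394] [3.3, 4.0, 4.7]
        FT: 0.306
        CT: 0.394
     T_tot: 1.706
 RMSa_foot: 74.642
 RMSw_foot: 776.404
wpeak_foot: 1142.921
```

The three take-off/landing pairs are recovered within a few milliseconds
of the generator's ground truth; the second hop's flight (0.306 s) and
contact (0.394 s) match the configured 0.30/0.40 s, and the risk-window
statistics (acceleration RMS in m/s², angular rates in °/s) are in the
range typical of healthy athletes hopping ~5 m.

Reliability statistics work on an n-subjects × k-trials matrix:

```python
m = np.array([[9, 2, 5], [6, 1, 7], [8, 4, 6], [7, 1, 2]], float)
r = icc_absolute_agreement(m)
print(f"ICC {r.icc:.4f}  CI [{r.ci_low:.4f}, {r.ci_high:.4f}]  "
      f"p={r.p:.4f}  SEM {r.sem:.3f}  MDC {r.mdc:.3f}")
print(round(lsi(4.91, 4.94).lsi, 2))           # hop-distance symmetry, %
print(sample_size_reliability(0.3, 0.7, 0.05, 0.8, 3))
```

```
ICC 0.0567  CI [-0.0582, 0.6624]  p=0.2561  SEM 2.710  MDC 7.513
99.39
16
```

An ICC near zero with a wide CI says these four subjects' trials are
dominated by within-subject variability; the MDC (7.5, same units as the
measurements) is the smallest change a follow-up could distinguish from
measurement error. An LSI of 99.4% is well inside the 85–115%
physiological symmetry band, and 16 subjects suffice to show reliability
0.7 against a null of 0.3 with three repetitions (α = 0.05, power 0.8).

## Command line

```bash
kneestab simulate --task cht --n-subjects 17 --n-trials 3 --seed 1 --out data/
kneestab process --manifest data/manifest.csv --out out/
kneestab reliability --features out/features_tidy.csv --out report/
kneestab report --reliability-json report/reliability.json
```

`simulate` writes signal CSVs (columns `t, ax..az, gx..gz, mx..mz`, SI
units), ground-truth JSON sidecars and a manifest; `process` runs
preprocessing → segmentation → features; `reliability` computes the
cohort tables (per-subject medians over trials, cohort mean ± SD, ICC/CI/
SEM/MDC per parameter and limb, per-subject LSI).

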