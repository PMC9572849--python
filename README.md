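# pushpull

Analysis pipeline for studying how operators' psychological status and
upper-limb/spine pain syndromes shape the execution of a repetitive
industrial task: pushing and pulling (P&P) a ~100 kg handcart around an
8-waypoint circuit. The package is aimed at occupational-biomechanics
and ergonomics researchers who record bilateral 3-axis handle forces
and surface EMG during such sessions and want a reproducible path from
raw channels to group-contrast tables.

## What it computes

**Cohort classification.** Participants are scored on the DASS-42
(three 14-item scales, items 0–3, totals 0–42) plus a 14-item apathy
scale, and examined clinically (active trigger points on a 0–4 verbal
rating scale, thoracolumbar range of motion, straight-leg raise). Two
extreme groups are formed: Group 1 (no psychometric total at/above its
cut-off — stress ≥ 15, anxiety ≥ 8, depression ≥ 10, apathy ≥ 14 —
no active trigger points, normal spinal mobility) and Group 2 (≥ 2
high totals, ≥ 2 active trigger points, reduced mobility).

**Signal processing.** Per handle side the resultant force is
F = √(fx² + fy² + fz²). EMG channels (latissimus dorsi, pectoralis
major, flexor carpi ulnaris, bilateral) are band-pass filtered
(zero-phase Butterworth, 20–450 Hz clipped below Nyquist), full-wave
rectified, smoothed (100 ms moving average) and normalized to each
muscle's maximal voluntary contraction (MVC), extracted as the maximum
of the identically processed MVC-trial envelope.

**Segmentation.** Each traversal's eight waypoint events
(① ② ③ ④ ⑤ ⑥ ⑦ ①) define six overlapping phases (P1-2-3 … P6-7-1).
A phase's analysis window is the last 30% of its first leg plus the
first 70% of its second leg; time inside the window maps
piecewise-linearly onto a relative-moment scale, −1 at the window
start, 0 at the middle waypoint, +1 at the window end.

**Features.** Per window and side: mean, SD, max, min, time integral
(∫F dt, trapezoidal), relative moments of max and min, maximal
difference of consecutive extrema, and local-extrema counts
(prominence ≥ 5% of the window range, ≥ 0.1 s apart). Per phase:
overall duration, position-related task time, relative moment of the
middle event. Per window and EMG channel: the mean absolute value
(MAV) of the MVC-normalized envelope.

**Contrasts.** Group means are pooled over all
(participant, traversal, phase) cells; every contrast is a percent
difference (value − reference)/reference × 100 with Group 1 (or the
first two traversals, S1–2) as the reference. No inferential
statistics are computed.

**Simulator.** Because the motivating study's raw recordings were
never deposited, the package includes a seeded synthetic session
generator that emulates the protocol (5 series × 2 attempts, 2 s /
20 s pauses, ~8.9 s legs, 100 Hz) with controllable group effects
(effort scale, left/right asymmetry, peak-timing shift, micro-peak
rate, fatigue drift, per-channel MAV targets), so every pipeline stage
is testable by parameter recovery.

## Worked example

```python
from pushpull import (simulate_cohort, label_cohort, analyze_participant,
                      aggregate_group, build_report, series_contrast,
                      group1_reference_config, group2_reference_config)
import pandas as pd

records, sessions = simulate_cohort(
    2, 3, group1_reference_config(), group2_reference_config(), seed=1)
labels = label_cohort(records)
tables = []
for pid, sp in sessions.items():
    t = analyze_participant(sp.recording, sp.mvc_trials)
    t.insert(0, "participant", pid)
    tables.append(t)
features = pd.concat(tables, ignore_index=True)
report = build_report(aggregate_group(features, labels),
                      series_contrast(features, labels))
print(report.loc[["Fintright", "Fmeanright", "overall duration"],
                 ["group1_mean", "group2_mean", "pct_diff_g2_vs_g1"]])
```

prints

```
                  group1_mean  group2_mean  pct_diff_g2_vs_g1
parameter
Fintright           26.985757    55.569142         105.920261
Fmeanright           3.173267     6.287761          98.147896
overall duration    17.047696    17.701143           3.833053
```

With the reference configurations (Group 2 effort scaled 1.9×), the
recovered force-integral contrast is close to +90–110%, the per-window
force means sit on the ~3 force-unit scale, and the high-score group's
phases last slightly longer — the qualitative signature the pipeline
is designed to expose. The same end-to-end run is available from the
shell:

```bash
pushpull run --config examples/cohort.yaml --seed 1 --out out/
pushpull score --participants src/pushpull/data/participants.csv --out labels.csv
```

(any of `simulate`, `score`, `segment`, `extract`, `compare`, `run`).

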