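# wheelpa

Wheelchair physical-activity metrics from wearable sensor streams: a
computation stack that goes from raw wrist-accelerometer (30 Hz), heart-rate
(1 Hz) and wheel-rotation (5 Hz) CSV streams to per-minute features, daily
physical-activity summaries, sedentary alerts, valid-day filtering, and a
pre/post group analysis — plus a labeled simulator so the whole pipeline is
testable at desk scale without any device.

## Modules

| module | what it does |
| --- | --- |
| `wheelpa.synthetic_data` | labeled activity schedules rendered into realistic multi-rate streams (intensity bands, push bursts, wheel rotations, battery-death gaps) |
| `wheelpa.stream_ingest` | CSV stream parsing, 1440-slot minute gridding, gap inference, wear coverage |
| `wheelpa.minute_features` | per-minute MAD of the acceleration magnitude, push counting, rotation→distance, energy estimate |
| `wheelpa.daily_metrics` | intensity classification, MVPA minutes, 30-minute-window sedentary breaks, alerts, goal progress |
| `wheelpa.study_analysis` | valid-day rule, phase means, ±10 % change classification, Wilcoxon signed-rank / paired t, report table, power analysis |

A 16-participant pre/post cohort (`wheelpa/data/prepost_cohort.csv`: daily
exercise time, sedentary breaks, travel distance, exercise self-efficacy
score for baseline and intervention phases) ships with the package; all
group statistics in the report are recomputed from its per-participant
values at run time.

Intensity cut-points, the push detector and the energy model are explicit,
configurable placeholders — the deployed algorithms they stand in for are
unpublished. Group-level analysis results do not depend on them.

## CLI

```sh
# generate a labeled 7-day simulation (streams + daily log + ground truth)
wheelpa simulate --days 7 --seed 1 --out scratch/sim

# per-day metrics from raw streams (YAML config optional)
wheelpa process --input scratch/sim --out scratch/sim/metrics.csv

# pre/post group analysis on the packaged cohort (or --input your_cohort.csv)
wheelpa analyze --fixture --report report.csv
```

`process` accepts a single YAML config with sections `demographics`,
`thresholds`, `push_detector`, `energy_model`, `goals` and top-level keys
`wheel_diameter_m`, `break_rule` (`nonsedentary` | `mvpa_only`) and
`coverage_floor`; every effective value is echoed to the run log.

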