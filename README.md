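# gaitclamp

A tested re-implementation of a "clamp" walking experiment on a synthetic
cohort: a self-paced treadmill speed controller with propulsive-force
biofeedback, step-level ground-reaction-force and metabolic processing, and
the correlation / repeated-measures-ANOVA analysis linking peak propulsive
force (F_P), walking speed, and metabolic cost.

Real participants are replaced by a calibrated generator: virtual walkers
produce raw force-plate, heel-marker, belt-speed and breath-by-breath gas
exchange time series, and the downstream pipeline recovers the target group
statistics *from those raw signals* (waveforms → 20 N gait events → F_P/F_B
peaks → stride metrics → Brockway power → trial summaries → pooled
regressions and ANOVA).

## Modules

| module | role |
| --- | --- |
| `gaitclamp.synthetic_gait` | virtual participants and raw trials (fixed-speed "speed clamp" and closed-loop self-paced "F_P clamp"), calibrated response surfaces, residual SDs derived from target R² values |
| `gaitclamp.selfpace_controller` | dead-zone proportional belt-speed controller (`ΔSpeed = R·D·L`, 20 cm dead zone, L = 0.1) and force-target biofeedback state |
| `gaitclamp.gait_processing` | heel-strike/toe-off detection (20 N threshold), F_P/F_B peak extraction, stride length/duration with belt-travel correction, final-2-min trial summaries |
| `gaitclamp.metabolics` | Brockway power from V̇O₂/V̇CO₂, time-weighted steady-state averaging, net metabolic power, cost of transport |
| `gaitclamp.stats_analysis` | per-clamp / clamp-averaged R² with strength labels, 2×5 repeated-measures ANOVA with ηp², Tukey post-hocs, paired Cohen's d, speed-variability check |
| `gaitclamp.cli` | orchestration (`simulate`/`process`/`analyze`/`all`/`validate`), YAML config, seeded reproducibility |

## CLI

```sh
# full experiment: 20 participants x (5 speed-clamp + 5 F_P-clamp) trials
gaitclamp all --seed 1 --outdir runs/demo

# smaller smoke run
gaitclamp all --seed 1 --n-participants 3 --trial-duration 150 --outdir runs/smoke

# write raw trial tables, then re-process them from text
gaitclamp simulate --seed 1 --n-participants 2 --trial-duration 150 --outdir runs/raw
gaitclamp process runs/raw/trials --out runs/raw/summary2.tsv

# analysis only, and target validation
gaitclamp analyze runs/demo/summary.tsv --outdir runs/demo/analysis
gaitclamp validate runs/demo
```

A run directory contains `summary.tsv` (one row per trial),
`associations.tsv`, `anova.tsv`, `speed_variability.tsv`, `report.txt`,
`headline.json`, and the resolved `config.yaml` plus its hash for exact
reproduction. Identical config + seed reproduces byte-identical outputs.

## Notes

- All randomness flows from a single root seed through fixed per-purpose
  child streams (cohort / trial / standing-baseline), so every artifact is
  reproducible end to end.
- The calibration is explicit: residual SDs come from inverting
  `R² = var(signal) / (var(signal) + var(residual))` for the target pooled
  R² values (`gaitclamp.synthetic_gait.CalibrationParams.derived`), and a
  zero-noise configuration (`CalibrationParams.zeroed()`) closes the loop
  exactly (pipeline-recovered R² = 1, slopes equal the calibration slopes).
- Deliverables are plain text only: trial series as TSV, breath tables as
  TSV, sidecars as JSON, configs as YAML.
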