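# equirhythm

Rhythm analysis of exercising equine ECG tachograms: detection and
classification of premature complexes in RR-interval series from ridden
workouts, per-workout arrhythmia burden and heart-rate metrics, and
cohort-level descriptive tables and mixed-effects association models — plus
a synthetic cohort generator with ground-truth event ledgers so the whole
pipeline is testable end to end without device data.

## What it does

- **`equirhythm.io`** — tachogram / cohort-metadata / raw-ECG CSV dialects
  (integer-millisecond beat times, exact round trips), a simple band-pass +
  adaptive-threshold R-peak detector, duration-weighted readability and the
  ≥95 % inclusion rule.
- **`equirhythm.rhythm`** — the core detector: an RR interval deviating 5 %
  or more from the local reference (median of up to 11 nearest eligible
  neighbouring intervals, iterated to a fixed point with premature beats
  excluded, plus a rescue pass for long runs) marks a premature complex;
  consecutive prematures group into singles / couplets / triplets / runs;
  singles are classified by compensatory-pause arithmetic and relative QRS
  width; paroxysmal atrial-fibrillation segments are found from sustained
  RR variability with near-zero lag-1 autocorrelation; fast-deceleration
  phases are segmented from the smoothed heart-rate curve.
- **`equirhythm.summary`** — HR_peak (rate of the mean of the 5 shortest
  normal RR intervals), HR_mean (rate of the duration-weighted mean RR) and
  the per-workout results row.
- **`equirhythm.cohort`** — group × workout-type summary tables with counts
  and prevalences, Spearman correlations with Chan strength bands (exact
  permutation p for n ≤ 9), a collinearity screen (R² > 0.8 / VIF > 5), and
  random-intercept-per-horse logistic and Poisson models (Gauss–Hermite
  maximum likelihood; odds / incidence-rate ratios with 95 % CIs, pooled
  fallback on singular variance).
- **`equirhythm.simulate`** — cohort sampler, cosine-eased heart-rate
  trajectories, beat-series synthesis with truncated lognormal sinus
  variability, exact event injection (compensatory coupling + return = two
  base cycles), artifact windows and a complete ground-truth ledger.
- **`equirhythm.datasets`** — bundled published aggregate tallies of a
  62-horse eventing cohort used as table fixtures.
- **`equirhythm.pipeline` / `equirhythm.cli`** — seeded end-to-end runs
  with strict YAML configuration and a checksummed reproducibility
  manifest.

## CLI

```sh
equirhythm simulate  --config config.yaml --out out/ --seed 7
equirhythm analyze   --dir out/tachograms --meta out/cohort_metadata.csv --out out/
equirhythm analyze   --tachogram one_workout.csv --out out/
equirhythm summarize --dir out/tachograms --meta out/cohort_metadata.csv --out out/
equirhythm cohort    --results out/workout_results.csv --out out/
equirhythm run       --config config.yaml --out out/ --seed 7   # all stages
```

A minimal config enabling simulation:

```yaml
simulation:
  n_horses: 10
  cardiac_fraction: 0.2
  workouts_per_horse: [2, 8]
seed: 7
```

All analysis constants (detection threshold 0.05, reference window 11,
pause tolerance 0.05, pAF CV threshold 0.10, deceleration drop 30 bpm /
60 s, inclusion cutoff 0.95, 5-beat HR_peak) live in the config schema
(`equirhythm.config.PipelineConfig`) and nowhere else.

## Outputs

- `tachograms/*.csv` + `*.truth.json` — simulated beat series and ledgers
- `workout_results.csv` — one row per workout (metrics + flags)
- `group_summary.csv` — group × type table (n, nPC median/range,
  flag counts and percentages, HR medians/ranges)
- `associations.csv`, `models.json` — Spearman results and model estimates
- `manifest.json` — config echo, seed, per-stage SHA-256 checksums
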