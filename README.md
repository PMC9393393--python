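# swimprog

Weekly swimmer-progress monitoring from per-lap performance metrics.

Given per-session lap logs (five stopwatch lap times per session plus five
IMU-derived goal-metric velocities per lap: push maximum, glide end,
stroke-preparation average, free-swimming average and whole-lap average),
the package:

1. compares every pair of a swimmer's sessions with **Cliff's delta** and an
   asymmetric small-sample confidence interval (`swimprog.effect_size`);
2. derives a data-driven **meaningful lap-time change (MLTC)** threshold
   from session pairs three weeks apart, and labels a pair *meaningful
   progress* when its lap-time change is both significant and a decrease
   larger than the threshold (`swimprog.pipeline`);
3. scores each goal metric as a **detector of meaningful progress**
   (TP/TN/FP/FN association rules; accuracy, precision, sensitivity,
   specificity), pools effect sizes, and correlates per-pair metric changes
   with the lap-time change after discarding changes inside the metric's
   ±RMSE estimation-error band (`swimprog.assessment`);
4. ships a **synthetic cohort generator** with latent linear improvement,
   stopwatch error, absences, configurable metric/lap-time coupling and
   ground-truth progress labels (`swimprog.synthetic`), plus CSV I/O and a
   CLI (`swimprog.io`, `swimprog.report`, `swimprog.cli`).

## CLI

```sh
swimprog simulate --seed 1 --out out/sim            # synthetic cohort + ground truth
swimprog analyze --sessions out/sim/sessions.csv --out out/an
swimprog analyze --sessions out/sim/sessions.csv --mltc 0.5 --out out/an   # fixed threshold
swimprog report --pairs out/an/pairs.csv --out out/fig                     # delta histograms
swimprog run --config config.yaml --seed 1 --out out/full                  # end to end
```

`run` takes a single YAML config, e.g.

```yaml
seed: 1
confidence_level: 0.95
synthetic: {n_swimmers: 16, n_sessions: 10}   # or: input_csv: path/to/sessions.csv
mltc: {mode: derive}                           # or: {mode: fixed, value: 0.5}
rmse: {push_vmax: 0.10, glid_vend: 0.10, stpr_vavg: 0.10, swim_vavg: 0.03, lap_vavg: 0.02}
plots: true
```

and writes the comparison-pair table, per-metric detection scores,
effect-size summary, delta-correlation table, delta histograms with ±RMSE
bands, and a JSON run log (seed, thresholds, exclusions).

## Library use

```python
from swimprog import (SyntheticConfig, generate_cohort, compute_mltc,
                      detect_progress, classify_pairs, detection_scores)

cohort, truth = generate_cohort(SyntheticConfig(seed=1))
mltc = compute_mltc(cohort)               # threshold from 3-week-apart pairs
pairs = detect_progress(cohort, mltc)     # two-step significant/meaningful labels
scores = {m: detection_scores(c, m) for m, c in classify_pairs(pairs).items()}
```

## Notes

- Significance is per comparison at the configured confidence level; no
  multiple-testing correction is applied across the session pairs (this is
  recorded in every run log).
- Scores with zero denominators (e.g. no positives) are reported as
  undefined, never as 0 or 1.
- The synthetic generator's distributional choices (Gaussian noise, linear
  trends, i.i.d. laps within a session) are modelling assumptions exposed
  through `SyntheticConfig`.
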