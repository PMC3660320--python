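# scmforage

Simulation and analysis toolkit for a race model of foraging choice: when an
animal meets two options at once, each option is processed independently and
the one whose latency process finishes first is taken — no comparison stage.
Preference in simultaneous choices is then predictable from the latencies
observed when each option is encountered alone.

The package provides:

- **`scmforage.scheduler`** — daily operant session plans: alternating
  two-option contexts, single-option and unrewarded peak trials interleaved
  pseudo-randomly (never two peak trials in a row), choice trials flanking
  each context visit in testing sessions, and the reward-rate-equalising ITI
  rule. Generated schedules validate against their own structural invariants.
- **`scmforage.synth`** — synthetic subjects: shifted-lognormal latencies
  whose log-median decreases with subjective value (immediacy plus
  within-context rank), a reaction-time floor that compresses high-value
  options, Gaussian-bump peak-trial peck trains with scalar spread, and
  choice trials resolved by the race itself (so the synthetic world is
  self-consistent with the predictor).
- **`scmforage.race`** — the race model proper: Monte Carlo preference
  prediction by resampling single-option latencies (default 10,000
  experiments of 96 trials), a quadrature oracle for parametric laws, and
  censored winner-latency summaries (the source of predicted choice-latency
  shortening).
- **`scmforage.stats`** — ECDF-area latency scores, shortening comparisons,
  one-sample preference tests on arcsine-square-root transformed
  proportions, paired log-median tests, and the session-stability rule
  (SD < 10 points, no trend, last three sessions).
- **`scmforage.peaks`** — peak-procedure analysis: binning, Gaussian peak
  fits, and paired comparisons of remembered delays between options.
- **`scmforage.pipeline`** — the end-to-end desk-scale run: train and test a
  cohort to stability, predict each subject's preferences from their own
  no-choice latencies, and compare observed versus predicted.

## CLI

```sh
scmforage schedule  --phase testing --pairing B:C --seed 1 --out sched.csv
scmforage simulate  --subjects 7 --days 3 --phase testing --pairing B:C \
                    --seed 1 --out logs/
scmforage predict   --logs logs/ --pairing B:C --n-experiments 10000 \
                    --n-trials 96 --seed 1 --out pred.json
scmforage analyze   --logs logs/ --what preference|shortening|stability --out out.json
scmforage peaks     --logs logs/ --out peaks/
scmforage reproduce --seed 1 --out run/            # full pipeline + manifest
```

All commands accept `--config config.yaml` (see `scmforage.config.FullConfig`
for the namespaces: `design`, `value`, `timing`, `scm`, `analysis`).
Every run is deterministic given (config, seed).

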