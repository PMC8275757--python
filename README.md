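# pupilkit

A pupillometry analysis pipeline for self-control research: from raw pupil
samples to the **Pupil Dilation Index (PDI)**, regulation-success scores,
regression models, and leave-two-participants-out prediction — plus a
synthetic cohort generator so every stage is testable without external data.

## What it does

1. **Preprocessing** (`pupilkit.preprocess`) — blink/loss detection (binary
   mask → Gaussian smoothing, FWHM 200 ms → box-car → segment bounds), linear
   interpolation, within-run z-scoring, stimulus-locked epoching with 500 ms
   pre-stimulus baseline correction, optional moving-average smoothing.
2. **Cluster statistics** (`pupilkit.clusterstat`) — per-participant
   Reappraise>View contrast, pointwise one-sample t curve, supra-threshold
   clusters (T = 3), max-cluster sign-flip permutation null, and the PDI
   (mean contrast over the significant window; fixed 3.4–5.6 s replication
   window or data-driven).
3. **Behavioural scores** (`pupilkit.scores`) — reappraisal success (rating
   shift toward neutral, per valence then averaged), affective distance
   (mean |rating − 5|), dietary health-challenge success (percent
   self-controlled challenge choices).
4. **Inference** (`pupilkit.inference`) — linear models with a flat-prior
   analytic Bayesian engine (posterior means coincide with OLS) and an OLS
   engine, JZS and BIC Bayes factors, Bayesian-flavoured Spearman rank
   correlation, and a BEST-style paired comparison.
5. **Prediction** (`pupilkit.prediction`) — all C(n,2) leave-2-out splits,
   pairwise ordering accuracy, and a sign-flip permutation null for it.
6. **Synthetic cohorts** (`pupilkit.synthcohort`) — latent-capacity
   generative model producing pupil runs (arousal transient + regulation
   ramp/plateau + AR(1) noise + blinks), SAM ratings, and dietary choices.
7. **I/O + CLI** (`pupilkit.io_cli`) — CSV/JSON schemas, YAML pipeline
   config, manifest with config hash, and the `pupilkit` command.

## CLI

```bash
pupilkit run-all --seed 0 --outdir out          # simulate-first full pipeline
pupilkit simulate --seed 1 --outdir sim         # write a cohort CSV bundle
pupilkit preprocess --samples sim/samples.csv --events sim/events.csv --out contrast.csv
pupilkit cluster --contrast contrast.csv --out cluster.json
pupilkit pdi --contrast contrast.csv --out pdi.csv
pupilkit score --ratings sim/ratings.csv --choices sim/choices.csv \
    --pdi pdi.csv --demographics sim/demographics.csv --out scores.csv
pupilkit model --scores scores.csv --out models.json
pupilkit predict --scores scores.csv --out prediction.json
```

Exit codes: 0 ok, 1 configuration error, 2 data error.  A YAML config
(`--config`) mirrors `pupilkit.io_cli.PipelineConfig`; all seeds are
explicit and echoed into `manifest.json` together with a config hash and
per-artifact checksums, so reruns are byte-identical.

### Data formats

CSV with header row, one table for all participants:

- `samples.csv`: `participant_id, t_ms, diameter, lost` (uniform time grid;
  `lost` ∈ {0,1}; a missing `lost` column defaults to all-valid).  Exports
  derived from EyeLink ASC files are ingested by mapping onto these columns.
- `events.csv`: `participant_id, trial_id, block_type, condition, valence,
  adaptation_onset_ms, stimulus_onset_ms, rating`
- `ratings.csv`: `participant_id, stimulus_id, valence, view_rating,
  reappraise_rating[, scale_reversed]`
- `choices.csv`: `participant_id, trial, challenge, food_type, choice`

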