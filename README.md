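# leadtime

Single-lead, time-resolved decoding and latency-timeline reconstruction for
response-locked electrophysiology, exercised end-to-end on synthetic
recordings with known ground truth.

The pipeline takes multi-lead trial signals locked to a button press and
produces:

1. **Spectral features** — complex Morlet wavelet power (4 cycles, 50
   geometric scales, 5–152 Hz) on a 10-ms grid over −0.5 … +0.15 s
   (`leadtime.spectral`), after zero-phase Butterworth band-pass (1.5–300 Hz)
   and line-noise notch filtering (`leadtime.prep`).
2. **Decoding traces** — a shrinkage-regularized LDA classifier trained per
   lead and per time bin on left vs right responses, cross-validated with
   repeated stratified 5-fold CV; out-of-fold decision values are combined
   into a pooled two-sample t-trace (df = N−2) with balanced label-shuffle
   permutation references (`leadtime.decode`). An activity-vs-baseline
   classifier (intact vs time-shuffled surrogates) and leave-one-out
   single-trial decision-value traces use the same machinery.
3. **Cluster statistics** — maximal supra-threshold runs of the t-trace,
   rank-tested against the pooled permutation cluster masses, with
   Benjamini–Hochberg FDR at q = 0.10; plus condition-trace comparisons,
   lead-count rank tests, and behavioral chi-squared / pooled-t helpers
   (`leadtime.stats`).
4. **Single-trial onsets** — three-step peak-onset detector (global
   extremum, 50-ms block smoothing, backward scan for the first
   below-half-height point whose slope stays under 5° for 30 ms), applied to
   decision-value traces and per-frequency power deflections
   (`leadtime.onset`).
5. **Timeline and consensus** — pairwise area onset-difference matrices
   (average-of-onsets and trial-by-trial routes), leave-one-lead-out
   bootstraps, an iterative 1-D MDS embedding (β = 0.9, exponential
   sigma-weighted updates, rank-stability stop rule), and a cross-method
   rank-conjunction test with clustering score C against label-shuffled
   nulls (`leadtime.timeline`).

The synthetic generator (`leadtime.synth`) emulates the rule-switching task
(blocks of 10–46 trials, 18-step cue grid over 300–600 ms, 1.5-s deadline)
and plants configurable band-limited left/right power contrasts with known
per-area onset times — optionally biphasic — on 1/f background noise, so
every downstream stage can be tested for parameter recovery.

## Test

```sh
python -m pytest -q tests/
```

The full suite (including the acceptance criteria in
`tests/test_acceptance.py`) takes ~10 minutes. One acceptance test,
`test_c4a_per_timebin_rate_matches_alpha`, fails by design: cross-validated
decision values are not independent draws, so the parametric per-timebin t
calibration demanded by that criterion does not hold for this estimator —
the permutation-based cluster inference the pipeline actually uses is
calibrated (see `test_c4b_fdr_cluster_rate_at_most_nominal`).

## CLI

```sh
leadtime run -c config.yaml -o runs/demo     # full pipeline
leadtime simulate -c config.yaml -o runs/sim # synthetic recording only
leadtime report -o runs/demo                 # summarize a run directory
```

A config file is YAML with sections mirroring the module configs:

```yaml
seed: 7
synth:
  n_trials: 120
  n_leads: 12
  area_assignment: [P1, P1, P1, P2, P2, P2, P3, P3, P3, N, N, N]
  effects:
    P1: {onset: -0.20, band: [25, 45], amplitude: 0.85}
    P2: {onset: -0.15, band: [25, 45], amplitude: 0.85}
    P3: {onset: -0.10, band: [25, 45], amplitude: 0.85}
spectral: {f_min: 15, f_max: 60, n_scales: 8}
decode: {n_repeats: 2, n_permutations: 20}
```

Outputs are TSV/JSON tables (classifier traces, clusters, onsets, timelines,
rank conjunction) plus an HDF5 epoch container and a `provenance.json` with
the config hash and per-stage timings. Exit codes: 0 success, 2 config
error, 3 stage failure.

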