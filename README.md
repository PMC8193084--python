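# eeglrtc

Single-trial long-range temporal correlation (LRTC) analysis of EEG-like
signals: sliding-window detrended fluctuation analysis (DFA) of broadband
activity, a three-stage LRTC validation cascade, stitched alpha-envelope
LRTC at long timescales, group time-course statistics, and per-window LDA
classification of task vs rest — exercised end-to-end on a synthetic EEG
generator with known ground-truth Hurst dynamics.

## What's inside

| Module | Purpose |
|---|---|
| `eeglrtc.synth` | Exact fGn (circulant embedding), ARFIMA simulation, amplitude-modulated 10 Hz component, trial/dataset generators with ground truth |
| `eeglrtc.prep` | Zero-phase Butterworth band-pass, polyphase resampling, causal 2 s / 100 ms sliding windows (Hanning), Hilbert alpha envelope, cross-trial stitching, exponential smoothing |
| `eeglrtc.dfa` | Integrated-profile DFA with 25 log2-spaced box sizes in [10, N/4], forward/backward averaging, per-window H time courses, stitched-segment DFA |
| `eeglrtc.validate` | Surrogate shuffle test, fractional differencing with d = H − 0.5, ARMA-vs-ARFIMA AIC contest (p = 1..10, q = 0), ML-DFA power-law linearity competition, R² |
| `eeglrtc.groupstats` | Grand averages, KS-normality-gated t/Mann-Whitney per-window tests, significant intervals, H_BB-H_alpha correlation |
| `eeglrtc.classify` | Per-window LDA, repeated stratified k-fold and leave-one-participant-out CV, exact binomial chance thresholds, peak/crossing/lead times |
| `eeglrtc.io` / `eeglrtc.edf` / `eeglrtc.cli` | Delimited + EDF+ readers/writers, YAML config, CLI |

## CLI

```bash
# full chain into a run directory (simulate -> prep -> lrtc -> validate
# -> stats -> stitched alpha -> classify, with a reproducibility manifest)
eeglrtc run --config cfg.yaml --out runs/demo --seed 1

# or stage by stage
eeglrtc simulate --config cfg.yaml --out data/ --seed 1 --edf
eeglrtc lrtc     --input data/dataset.csv --out data/h.csv
eeglrtc stats    --input data/h.csv --out data/stats.csv
eeglrtc classify --input data/h.csv --out data/cls.csv --seed 0
eeglrtc validate --input data/dataset.csv --out data/validation.json
```

A config file is optional; every key has a default (0.5-45 Hz band,
128 Hz, 2 s windows at 100 ms, 25 box sizes, 10x10-fold CV). Unknown
keys are rejected. Example:

```yaml
synth:
  n_trials_per_condition: 40
  h_rest: 0.60
  h_move: 0.75
prep:
  step: 0.1
seed: 1
```

## Conventions

Time is in seconds relative to the trial event (onset/cue) at 0; sliding
windows are labelled by their causal end time (the window at `t` spans
`[t-2, t]`); sample indexing is 0-based half-open. All randomness flows
through explicit integer seeds.
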