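# eegcog

An EEG analysis pipeline that predicts post-stroke cognitive outcome from
resting-state brain-network features, plus a synthetic-cohort generator with
known ground truth so every stage is testable without clinical data.

The chain: 19-channel resting EEG → band-pass (1–45.5 Hz) + notch + common
average reference + epoch rejection → Welch spectra, 8 band powers
(absolute/relative) and TAR/TBR/TBR2/DAR ratios per channel → standardized
minimum-norm (sLORETA-style) source estimation onto 68 Desikan–Killiany ROIs
→ per-band imaginary-coherence (iCOH) connectivity → proportional
thresholding (top 25% of edges) → graph metrics (global efficiency,
characteristic path length, clustering, modularity, nodal variants) → a
two-stage model: (1) lesion-laterality classification with bilateral-subject
assignment, (2) per-group Pearson correlation filter (|r| > 0.3),
tree-ensemble importance ranking, top-20 selection, and leave-one-out
regression (ridge/lasso/elasticnet/SVR/AdaBoost) scored by R² on the pooled
LOO predictions, with a composite-subset sensitivity search.

## CLI

```bash
eegcog print-config                  # all defaults as YAML
eegcog simulate --seed 1 --out runs/cohort     # synthetic cohort on disk
eegcog preprocess subject.edf        # filter/re-reference/epoch one file
eegcog features subject.edf          # full feature row (spectra + network)
eegcog laterality features.csv       # LOO laterality classification
eegcog select features.csv           # correlation filter + importance + top-k
eegcog fit features.csv --models ridge,lasso   # LOO regression R²
eegcog sensitivity features.csv      # composite-subset search
eegcog run-all --seed 1 --out runs/demo        # simulate + every stage
eegcog report runs/demo              # summarize a run directory
```

`run-all` writes `features.csv`, `laterality.json`, `models.json` and a
provenance `manifest.json` (config, config hash, seed, package version) from
which the run is re-derivable.

Configuration is a strict-keyed YAML file (`eegcog print-config` shows the
schema); defaults mirror the method's stated parameters: 250 Hz sampling,
1–45.5 Hz band-pass, 8 bands (delta 1–4 … gamma 30–45 Hz), 25% network
density, r threshold 0.3, top-20 features, LOO validation.

## Synthetic cohorts

`eegcog.synth` generates cohorts in two modes:

- `features`: subjects × the full 1120-column network-feature layout with
  chosen features "planted" into a noisy linear outcome (fast path for
  modeling tests);
- `eeg`: per-subject 68-ROI band-limited stochastic sources with
  phase-lagged theta coupling (nonzero iCOH at chosen pairs), a
  delta+theta amplitude excess on the lesioned hemisphere encoding
  laterality, projection to the 19 standard 10-20 electrodes through a
  schematic leadfield, and EDF export.

All randomness derives from a single cohort seed via
`numpy.random.SeedSequence.spawn`; identical seeds give bit-identical
cohorts.

## Layout

```
src/eegcog/
  bands.py          8-band scheme (half-open intervals)
  rois.py           packaged 68-ROI Desikan–Killiany table (+ data/dk_rois.csv)
  io.py             minimal 16-bit EDF codec, delimited matrices
  preprocess.py     band-pass/notch, CAR, epoching + amplitude/variance rejection
  spectral.py       Welch PSD, band powers, power ratios
  source.py         standardized minimum-norm inverse, ROI aggregation
  connectivity.py   cross-spectra, iCOH, proportional threshold, graph metrics
  synth.py          synthetic cohorts, coupled sources, leadfields
  modeling.py       laterality, selection, LOO regression, composite search
  config.py         strict-keyed run configuration
  pipeline.py       stage orchestration + provenance manifest
  cli.py            click CLI
```
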