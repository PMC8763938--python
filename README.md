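# dualpath

Analysis toolkit for dual-pathway hippocampus→prefrontal-cortex circuit
data. The package implements, with synthetic-data generators and attached
ground truth for every stage:

- **`dualpath.synthgen`** — seeded generators: a two-carrier
  amplitude-modulated fiber-photometry session (calcium-like transients,
  slow bleaching, shared autofluorescence artifact), two-layer cell maps on
  the straightened hippocampal axis, light-evoked synaptic sweep sets, and
  semi-Markov elevated-plus-maze (EPM) trajectories.
- **`dualpath.photometry`** — quadrature lock-in demodulation of
  frequency-multiplexed recordings (default carriers 210 Hz → green,
  500 Hz → red), 50 Hz downsampling, 3rd-order polynomial detrending,
  cross-frequency autofluorescence regression and session z-scoring.
- **`dualpath.perievent`** — 12 s / 20 s event-aligned epochs, bl/pre/post
  window statistics with event-type-specific post windows,
  superficial−deep difference scores, first/middle/last entry splits, and a
  step-down Šidák (Holm–Šidák) correction helper.
- **`dualpath.layers`** — Gaussian-mixture clustering (k = 1..6, BIC
  selection) of cell coordinates into radial layers, tracer-subset layer
  fractions, colocalization, intensity profiles, reference-line Sholl
  analysis and SWC morphometrics.
- **`dualpath.cracm`** — light-evoked response amplitudes (1 ms window
  around the peak of the averaged trace), the 6×SD connectivity rule,
  paired log-ratios, and intrinsic features (spike counts, bursting, sag,
  membrane time constant, AP half-width) with fast-spiking classification.
- **`dualpath.epm`** — maze-zone classification, debounced arm-entry
  detection, per-epoch open-arm metrics, and the position-triggered latched
  closed-loop stimulation gate (plus the constant-stimulation variant).
- **`dualpath.pipeline`** — a seeded end-to-end demo run with a JSON
  manifest, and schema-validating readers for all supported formats.

## Command-line interface

```bash
dualpath demo --seed 0 --out demo_out          # full synthetic study
dualpath synth --what cellmap --out data/      # generate synthetic inputs
dualpath layers fit --cellmap data/cellmap.tsv --out model.json
dualpath photometry process --input rec.h5 --out processed/
dualpath epm metrics --track data/track.csv --out metrics.json
dualpath cracm detect --sweeps sweeps.csv --out results.csv
```

`dualpath demo` chains every stage on seeded synthetic data and writes
per-stage CSV outputs plus `manifest.json` with seeds and checksums; the
same seed reproduces the manifest bit for bit.

## File formats

Recordings: HDF5 (`/raw`, `/fs`, `/carriers`) or CSV + TOML sidecar.
Cell maps and event tables: TSV. Sweep sets: wide CSV + TOML sidecar.
Tracks: CSV + TOML geometry. Morphologies: SWC. All readers validate their
schema and report the offending row/field on failure.
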