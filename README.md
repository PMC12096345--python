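# hsfkit

Hybrid fluorescence/reflectance spectral fingerprinting toolkit: a
physics-based simulator of a 12-LED portable fluorimeter, the exact
preprocessing pipeline that turns raw scans into 66×66×1 fingerprints,
and a CNN + classical-ML classification protocol over
drug–variant–concentration classes.

## What it does

- **`hsfkit.device`** — simulates per-LED emission spectra as a
  reflected excitation line (attenuated by a Beer–Lambert
  "pseudoabsorption" exponent) plus inner-filtered fluorescence and
  seeded detector noise; runs the auto-integration loop that drives the
  brightest pixel to 80% of detector saturation; assembles full raw
  scans of 18,192 rows × 5 fields (12 LED blocks × 1516 emission
  pixels on [185, 655] nm).
- **`hsfkit.compounds`** — a parametric (Gaussian-band) fluorophore
  registry with named entries tuned to documented spectral positions
  and a deterministic procedural pool for filler classes.
- **`hsfkit.preprocess`** — the five-step pipeline: exposure
  normalization, nonspectral-column removal, wavelength trimming
  (default [250, 655] nm), contiguous bin averaging (default 360
  bins/channel), per-channel [0, 1] min–max normalization, and
  zero-padding + reshape to 66 × 66 × 1.
- **`hsfkit.dataset`** — the default 86-class registry (1470 raw
  examples), library generation, oversampling with replacement to 20
  per class (→ 1720), and the seeded shuffled 80/20 split (1376/344).
- **`hsfkit.models`** — a pure-NumPy CNN (three conv/ReLU/max-pool
  stages, dense ReLU layers, softmax output; Adam) plus one-vs-rest
  logistic-regression / random-forest / SVM baselines searched over
  regularization strengths {0.0 … 1.0}, SVM kernels {linear, poly,
  rbf, sigmoid} and PCA widths {25, 50, 75, 100}; evaluation reports
  accuracy and macro precision/recall/F1 with confusion matrices.
- **`hsfkit.cli` / `hsfkit.experiment`** — an end-to-end command-line
  surface with a one-command seeded reproduction of the experiment.

## CLI

```bash
# one full raw scan (18,192 rows, CSV)
hsfkit simulate -c diazepam:0.5 --seed 1 --out scan.csv

# scan -> 66x66 fingerprint
hsfkit preprocess --in scan.csv --out fp.csv --trim 250 655 --bins 360

# build a fingerprint library with a manifest
hsfkit dataset build --registry default --seed 17 --out lib/

# train / evaluate / predict
hsfkit train --model cnn --seed 17 --out model/
hsfkit predict --scan scan.csv --model-dir model/

# the whole experiment, all four models, one seed
hsfkit run-all --models lr,rf,svm,cnn --seed 17 --out run/
```

`run-all` logs every stage with counts (1470 → 1720 → 1376/344 on the
defaults) and writes `manifest.json` (config hash, seed, per-model
metrics) plus a four-metric comparison table. `--grid full` enables the
complete stated hyperparameter grid for the baselines; the default
`quick` grid fits one representative candidate per algorithm.

Custom device parameters and class registries are YAML files; see
`hsfkit.io.write_device_config` / `hsfkit.dataset.write_registry` for
the schema (they emit annotated, round-trippable documents).

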