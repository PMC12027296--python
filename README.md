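# specfresh

VNIR hyperspectral chemometrics for chilled-meat freshness grading:

- **spectra_io** — spectral cube container with dark/white reference frames,
  reflectance calibration `G = (I - B) / (W - B)`, random non-overlapping
  ROI extraction (one mean spectrum per ROI), CSV/TSV spectrum tables and a
  minimal ENVI-style cube reader/writer.
- **preprocessing** — the five classic operators (SNV, MSC, Savitzky–Golay
  smoothing, first derivative, moving average) as pure, composable,
  label-preserving transforms.
- **feature_selection** — plug-in mutual-information estimation (bits,
  equal-frequency binning), marginal-MI band ranking, interaction-aware
  forward selection via joint MI (finds purely synergistic band pairs),
  exact Shapley attribution by subset enumeration, and a regression harness
  (R², RMSE, MAE, RPD).
- **grading** — threshold cross-classification of (TVB-N, TAC, MPN) triples
  into four freshness grades, with a severity policy for off-table triples
  and a configurable coarse/fine hierarchy.
- **model** — a dual-branch attention classifier in pure NumPy (a small
  reverse-mode autodiff engine lives in `model/autodiff.py`): sinusoidal
  band-position encoding, bidirectional cross-attention between a global
  (downsampled full-spectrum) branch and a local (selected-band) branch,
  multi-scale token pooling feeding four role-masked attention heads, and a
  hierarchical coarse/fine read-out trained with a dynamically weighted
  joint cross-entropy.
- **training** — stratified 4:1:1 splitting and k-fold CV, Adam training
  loop with early stopping, weighted precision/recall/F1 metrics from
  confusion counts, and a module-toggle ablation runner.
- **synthetic** — reproducible 14-day spoilage simulator: monotone indicator
  kinetics, chromophore-linked absorption bands on a smooth reflectance
  baseline, multiplicative scatter/tilt/noise, grade labels, and optional
  mini-cubes for exercising the calibration path.

## CLI

```bash
specfresh simulate --days 14 --per-day 200 --seed 0 --out data.csv
specfresh preprocess --method snv --in data.csv --out snv.csv
specfresh select --method mim --target label --k 12 --in snv.csv --out bands.json
specfresh train --selection bands.json --in snv.csv --model-out model.npz
specfresh evaluate --model model.npz --in snv.csv
specfresh ablate --selection bands.json --in snv.csv --out ablation.csv
specfresh cv --selection bands.json --in snv.csv --folds 5
```

Module ablations mirror the toggle grid (`--disable pbca|msmha|hcm`); with
all three disabled the network reduces to a concatenate-and-MLP baseline
over the two branch summaries.

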