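# pyroplast

Automated identification and semi-quantification of plastics in TGA-FTIR
(thermogravimetric analysis coupled with infrared spectroscopy of the evolved
gases) data. A heated sample releases volatile decomposition products in
material-specific temperature windows; `pyroplast` preprocesses the resulting
temperature-resolved FTIR spectra, identifies the materials present — by a
temperature-penalized spectral matching algorithm (SMA) and/or multilabel
one-vs-rest classifiers — and apportions the measured mass loss among the
identified materials.

## What's inside

| module | role |
| --- | --- |
| `pyroplast.core_model` | domain types (runs, spectra, libraries), CSV-matrix / JCAMP-DX / HDF5 I/O, library correlation diagnostics |
| `pyroplast.preprocess` | asPLS baseline correction, CO2/OH window masking, SNV, transfer-line temperature offset, TG/FTIR alignment, DTG, Gram–Schmidt trace |
| `pyroplast.sma` | hit quality r = mean(raw Pearson, derivative Pearson) with a Gaussian (or linear) penalty on the data-vs-reference temperature gap; iterative residual re-matching for mixtures |
| `pyroplast.ml_pipeline` | ANOVA F-test feature selection, EMSA data augmentation, one-vs-rest kNN/MLP/RF/SVC training with grid-search CV, per-spectrum probability maps |
| `pyroplast.synthetic_data` | 12 parametric pseudo-polymer archetypes (fixture library) and the mixture-thermogram generator with ground-truth manifests |
| `pyroplast.evaluation` | thermogram-level multilabel metrics: per-class precision/recall/F1, macro F1, Hamming accuracy; identifier benchmarking |
| `pyroplast.quantification` | label-map segmentation, MCR-ALS apportionment of mixed segments, DTG integration into per-class mass loss and relative compositions |
| `pyroplast.cli` | `pyroplast` command with subcommands for every stage plus an end-to-end `demo` |

Everything runs without measured data: the fixture archetypes generate
libraries, runs and mixtures with known ground truth.

## CLI quick tour

```bash
# generate the fixture library and its single-material runs
pyroplast synth fixtures --out fixtures/ --seed 0

# preprocess a raw CSV run (wavenumber column + one column per spectrum,
# header row of temperatures, TG sidecar <stem>.tg.csv)
pyroplast preprocess --in run.csv --out run.h5

# spectral matching
pyroplast match --run run.h5 --library fixtures/library.h5 \
    --threshold 0.7 --penalty gaussian:50 --out result.json

# train a classifier and produce a probability heatmap
pyroplast train --library fixtures/library.h5 --model svc --seed 17 --out model.bin
pyroplast classify --model model.bin --run run.h5 --out heatmap.csv

# synthetic mixture dataset + benchmark + quantification
pyroplast synth mixtures --n 100 --seed 7 --out dataset/
pyroplast evaluate --dataset dataset/ --models model.bin \
    --sma fixtures/library.h5 --out table.csv
pyroplast quantify --run dataset/mix-00000.h5 --library fixtures/library.h5 \
    --out quant.json

# or everything at once
pyroplast demo --seed 1 --out demo/
```

Stage parameters live in a TOML config (`--config cfg.toml`) with sections
`[preprocess]`, `[train]` and `[sma]`; every artifact embeds the package
version, seed and a config hash.

### Run CSV dialect

The first header cell is `wavenumber`; every other header cell is the spectrum
temperature in °C. The first column holds strictly increasing wavenumbers
(cm⁻¹); each remaining column is one spectrum. TG data rides in a sidecar
`<stem>.tg.csv` with columns `temperature,tg`. Single spectra can also be read
from AFFN-encoded JCAMP-DX files.

## Conventions and caveats

- Analysis is restricted to 800–4000 cm⁻¹; the CO₂ (2200–2400 cm⁻¹) and OH
  (3150–3500 cm⁻¹) windows are masked, not corrected, and never contribute to
  any score or feature.
- DTG is stored as a positive mass-loss rate (−dTG/dT).
- SNV uses the population (n) standard deviation.
- The FTIR temperature offset is `dwell_time × heating_rate` (≈0.42 °C at the
  2.5 s / 10 °C·min⁻¹ defaults); TG temperatures are not shifted.
- The Gram–Schmidt trace is computed as the root-sum-square of the
  baseline-corrected spectrum — equivalent in effect to orthogonalisation
  against pre-run background vectors once the background is removed.
- Quantification does not correct for per-material residual (char) mass, and
  within mixed segments the MCR spectral-contribution fraction is used
  directly as a mass-fraction proxy; treat compositions as screening-level
  estimates.
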