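# vocalid

Toolkit for analysing the development of vocal individuality in animal
calls. It covers the full chain from audio to statistics:

- **`vocalid.features`** — call segmentation from the amplitude envelope and
  extraction of eight descriptors per call (duration, mean per-frame RMS
  amplitude, peak frequency, 25/50/75% spectral energy quantiles, spectral
  centroid, spectral slope in dB/kHz).
- **`vocalid.synthetic`** — seeded generator of call datasets with known
  individual signatures, context effects and age-dependent divergence
  (feature tables and optional band-shaped noise waveforms), used as
  ground truth for every downstream stage.
- **`vocalid.pdfa`** — permuted discriminant function analysis: calls are
  classified to individuals by linear discriminant functions on balanced
  train/test splits; significance comes from permuting individual labels
  *within* behavioural-context blocks (restriction factor). Reports correct
  and cross-classified percentages, their permutation chance levels,
  relative cross-classification level and add-one permutation p-values.
- **`vocalid.identity`** — potential of identity coding (PIC: pooled
  corrected CV over mean within-individual corrected CV) per parameter and
  age class, OLS age trends, KMO factorability screening, Bonferroni
  thresholds.
- **`vocalid.dissimilarity`** — per-individual daily median profiles,
  dyadic Euclidean dissimilarity scores (0 = identical), and OLS age trends
  overall and per behavioural context.
- **`vocalid.pipeline`** / **`vocalid.cli`** — end-to-end orchestration with
  context filtering (calls in the `fed` context are excluded by default)
  and a CSV/JSON report bundle.

## CLI

```sh
# synthetic feature table (+ optional rendered WAVs)
vocalid generate --seed 1 --out features.csv [--audio wav_dir/]

# descriptors from annotated WAV recordings
vocalid extract --wav-dir wavs/ --annotations annotations.csv --out features.csv

# single analyses
vocalid pdfa --features features.csv --out pdfa.csv --pooled --n-perm 1000 --seed 1
vocalid pic --features features.csv --out pic.csv
vocalid dissim --features features.csv --out dissim.csv --context pooled

# full pipeline (filter -> pDFA per age class + pooled -> PIC -> dissimilarity)
vocalid run --config config.yaml --seed 1 --out results/
```

`vocalid run` writes `pdfa.csv`, `pic.csv`, `dissimilarity_records.csv`,
`dissimilarity_trends.csv`, `context_composition.csv` and `manifest.json`
(seed, config hash, per-age-class call counts with a conservation check,
Bonferroni family sizes and thresholds). Runs are byte-identical given the
same seed.

## Notes on conventions

- Permutation p-values use the add-one convention (b + 1)/(m + 1); with
  1000 permutations the smallest attainable p is 1/1001 ≈ 0.001.
- Each permuted dataset is scored by the *same* procedure as the observed
  data (same number of balanced selections), keeping the permutation test
  exchangeable and its type-I error calibrated.
- PIC uses the pooled-sample corrected CV in the numerator and |mean| in
  the CV denominator (spectral slope is negative-valued).
- Dissimilarity is the raw Euclidean distance between median profiles
  (0 = identical); a `max-minus-distance` variant and global z-scaling of
  parameters are available as options.
- Age classes are the closed seven-day bins 11–17, 18–24, 25–31, 32–38,
  39–45 days.
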