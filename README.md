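# ntaflow

Post-processing for non-targeted LC-HRMS (NTA) feature tables from paired
serum/urine cohort studies. The pipeline takes MS1 alignment exports (one
per electrospray ionization mode), MS2 spectra for pooled samples, an MSP
spectral library, and a sample manifest, and produces filtered, normalized,
batch-corrected abundance tables with compound annotations, differential
statistics, and an endogenous–exogenous chemical correlation network.

## Stages

1. **Feature filtering** — removal of adduct satellites linked to parent
   ions, laboratory-blank filtering, a 70% detection-frequency cutoff
   (detection = non-missing area above the 10,000 noise floor), and
   cross-polarity merging of [M+H]⁺/[M−H]⁻ pairs (±1.00782 Da; mass error
   ≤ 5 ppm, ΔRT < 0.5 min, greedy one-to-one by ppm error).
2. **Normalization** — urine abundances scaled by median-ratio creatinine
   correction; serum untouched.
3. **Below-MDL imputation** — missing areas drawn per feature from a
   Normal(median, sd) of the observed log10 areas, truncated above at the
   smaller of the observed minimum and the MDL, with a fixed seed.
4. **Batch correction** — parametric empirical-Bayes location/scale model:
   feature standardization preserving biological covariates (matrix ×
   outcome), method-of-moments priors across features, iterative posterior
   shrinkage of per-batch shift/scale effects.
5. **Annotation** — weighted-cosine MS2 matching against an MSP library,
   confidence levels 1–5 (1 = authentic standard, RT < 0.05 min and ions
   within 5 ppm; 2 = score > 90; 3 = 50 < score ≤ 90; 4 = MS2 but no
   match; 5 = no usable MS2), transfer onto the MS1 alignment (ΔRT ≤ 0.1
   min, ≤ 2 ppm), and source attribution over five categories.
6. **Statistics** — PCA with PC–covariate correlations, per-feature Welch
   t-tests with Benjamini–Hochberg adjustment, volcano classification
   (p < 0.05, |log₂FC| > 1.2), hierarchical-clustering matrices.
7. **Network** — Pearson correlations (|R| > 0.5) between endogenous
   metabolites and all other Level 1–2 compounds, with per-node
   preterm/term detection proportions; exported as node-link JSON and
   GraphML.

A synthetic-data module (`ntaflow.synth`) generates cohorts with planted
batch effects, below-MDL censoring, differential features, cross-polarity
ion pairs (plus decoy near-pairs), adduct satellites, correlation clusters,
and a spectral library exercising every annotation level, so the entire
pipeline is testable without any instrument data.

## CLI

Everything is reachable through the `nta` umbrella command (stage-specific
aliases `nta-sim`, `nta-io`, `nta-filter`, `nta-normalize`, `nta-annotate`,
`nta-stats`, `nta-network` are installed too):

```sh
# end-to-end run on synthetic data; byte-identical for a fixed seed
nta run --simulate --seed 17 --out runs/demo

# or from a YAML config describing real inputs
nta run --config pipeline.yaml --out runs/study

# generate a synthetic cohort as plain CSV/MSP files
nta sim --out sim/ --seed 17

# validate any input file
nta io validate sim/alignment_pos.csv --kind alignment
```

The run directory contains every intermediate table (canonical alignment
CSV), the fitted batch model, PCA summaries, annotation and differential
CSVs, the network exports, and `run_manifest.json` with per-stage feature
counts.

## Layout

```
src/ntaflow/
  chem.py        monoisotopic masses, ppm arithmetic
  types.py       FeatureTable, Spectrum, library entries, annotations
  io_formats.py  alignment CSV, manifest CSV, MSP, graph, YAML dialects
  synth.py       synthetic cohort / feature-table / spectra generators
  filtering.py   adduct, blank, frequency filters; ESI+/ESI- merging
  normalize.py   creatinine normalization, imputation, batch correction
  annotate.py    spectral matching, confidence levels, source attribution
  diffstats.py   PCA, Welch+BH, volcano, hierarchical clustering
  network.py     endogenous-exogenous correlation network
  pipeline.py    orchestration + run manifest
  cli.py         click CLI
```
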