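# nmropls

A 1D ¹H-NMR metabolomics analysis pipeline for two-group (treated vs
control) studies:

- **`nmropls.simulate`** — synthetic cohort generator: plasma-like spectra
  (sharp metabolite multiplets plus broad lipoprotein envelopes, lactate
  reference at δ1.33) and brain-extract-like spectra (TSP reference at δ0),
  with known planted log2 fold changes exported as a ground-truth table.
- **`nmropls.processing`** — referencing, 0.02-ppm sum-method binning,
  fixed-region exclusion masks (below 0.7 ppm, above 9.38 ppm, water/noise
  region, EDTA contamination for plasma), RSD-based noise-bin detection,
  total-area and TSP normalization.
- **`nmropls.multivariate`** — from-scratch PCA and OPLS-DA (one predictive
  component plus configurable orthogonal components), prediction, R²X/R²Y,
  and VIP scores.
- **`nmropls.validation`** — repeated stratified 10-fold cross-validation
  ensembles (accuracy / sensitivity / specificity / Q² per iteration,
  mean ± SEM with SEM = sd/√iterations), permuted-label null ensembles, and
  an empirical-p comparison.
- **`nmropls.report`** — VIP-ranked discriminant bins, shift-table
  annotation (ambiguities preserved, e.g. `Histidine/Phenylalanine`),
  direction-of-change tables with t-tests (Levene-gated pooled/Welch),
  significance stars, and Cohen's d.
- **`nmropls.pipeline` / `nmropls.cli`** — configuration, orchestration,
  CSV/JSON artifacts and sha256 provenance.

## CLI

```sh
# simulate a 15-vs-14 plasma cohort with planted effects
nmropls simulate --design plasma --out runs/sim --seed 1

# reference + bin + mask + normalize
nmropls process --in runs/sim --out runs/proc --matrix plasma

# true-label ensemble and permuted-label null
nmropls discriminate --in runs/proc --out runs/disc --matrix plasma \
    --folds 10 --iterations 100 --seed 1 --permute

# VIP-ranked annotated direction-of-change report
nmropls report --in runs/proc --out runs/rep --matrix plasma

# or everything from one config file
nmropls run-all --config config.yaml --out runs/full --seed 1
```

Named designs: `plasma` (strong lipoprotein/glucose-down,
isoleucine/creatine-up panel), `brain_strong` (broad cortex-like panel),
`brain_weak` (small glutamine/NAA shifts only). A YAML config can override
any `RunConfig` field, including an explicit `design:` mapping with custom
effects, noise, grid and group sizes.

## Notes

- All randomness flows through explicit seeds; cohorts, ensembles and
  report files are byte-reproducible under a fixed configuration.
- Exclusion flags are metadata: masked bin values are preserved for audit
  (this is what lets TSP normalization use the δ0 bin even though bins
  below 0.7 ppm are excluded from the feature set).
- Report p-values are unadjusted; the CSV output carries a
  Benjamini–Hochberg column as a clearly labeled extension.
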