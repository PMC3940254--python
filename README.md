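# tumorline

Quantitative characterization and classification of tumor lines from
immunohistochemistry (IHC) marker images and small-animal PET uptake
volumes:

- **`tumorline.ihc`** — marker-image quantification: threshold segmentation,
  staining fraction of the viable tumor area (necrosis excluded), BrdU-style
  labeling index, vascular density (structures/mm²) and perfused vessel
  fraction.
- **`tumorline.pet`** — SUV computation from activity concentration and
  injection metadata, automatic tumor-VOI delineation at 40% of SUVmax
  (26-connected component containing the maximum), SUVmax/SUVmean,
  tumor-to-muscle ratio, %ID/g.
- **`tumorline.texture`** — global first-order texture features: mean (IHC
  only), skewness and Shannon entropy of the intensity distribution inside
  the positive stained area (IHC, threshold-rescaled) or the tumor VOI
  (PET), with fixed-bin-width discretization (0.5 SUV / 25 rescaled units).
- **`tumorline.varcomp`** — one-way random-intercept variance decomposition
  per parameter (REML via 1-D profile optimization, plus a closed-form
  ANOVA method-of-moments estimator) reporting the within-line / total
  variance heterogeneity ratio, and pairwise-complete correlation matrices.
- **`tumorline.classify`** — Random-Forest tumor-line prediction (default
  20,000 trees, sqrt(p) variables per split) with OOB accuracy, repeated
  75/25 cross validation on **shared splits** so models can be compared with
  a paired t-test, median imputation, OOB permutation importance, and an
  exhaustive accuracy sweep over all combinations of 1–8 of the 9 IHC
  parameters.
- **`tumorline.synthetic`** — synthetic cohorts (hierarchical Gaussian
  between-/within-line structure with configurable heterogeneity ratios and
  sporadic missingness) and image/volume phantoms (blob stains, ribbon
  vessels, point nuclei, ellipsoidal hot regions) whose ground truth is the
  exactly rasterized quantity, enabling exact oracle tests.
- **`tumorline.io` / `tumorline.pipeline` / `tumorline.cli`** — CSV/TIFF/
  PNG/raw+JSON readers and writers, YAML-configured end-to-end pipeline
  with a digest manifest, and a `tumorline` command-line interface.

## CLI

```sh
tumorline simulate --seed 1 --out cohort.csv         # synthetic cohort + truth JSON
tumorline varcomp --table cohort.csv --out het.csv --correlation-out corr.csv
tumorline classify --table cohort.csv --n-trees 2000 --n-repeats 200 --out model.json
tumorline compare --results a.json b.json            # paired t-test on shared splits
tumorline sweep --table cohort.csv --n-trees 200 --n-repeats 50
tumorline quantify-ihc --image scan.tif --threshold 700
tumorline quantify-pet --volume vol.npy --muscle-mean 0.5
tumorline run --config config.yaml --outdir results  # full pipeline + manifest
```

`tumorline run` executes simulate → quantify → features → variance
decomposition → classification → comparison and writes `cohort.csv`,
`heterogeneity.csv`, `correlation.csv`, `accuracy.csv`, `importance.csv`,
`comparison.json` (optionally `sweep.csv`) plus a `manifest.json` with a
SHA-256 digest per output; identical config + seed reproduces the result
files byte for byte.

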