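# symperc

Tools for scoring planar reflection symmetry in images, modeling perceptual
dissimilarity data, diagnosing systematic model-perception mismatches, and
improving linear classifiers with symmetry features — all exercisable on
synthetic part-based stimuli, with no external datasets required.

## What's inside

| Module | Purpose |
| --- | --- |
| `symperc.stimuli` | Two-part object sets composed from random part libraries, Gabor banks, simulated pair-dissimilarity tables, PNG + manifest I/O |
| `symperc.symmetry` | Reflection-symmetry scores about arbitrary center axes, multi-axis profiles, pair-level symmetry strength, area ratios |
| `symperc.perceptfit` | Reaction-time to dissimilarity conversion, split-half reliability with Spearman-Brown correction, PCA reduction, weighted component-distance fits, model-combination fits, leave-one-experiment-out generalization |
| `symperc.residuals` | Signed residuals with ±1 sd flags, residual-covariate correlations (with bootstrap CIs), shared-part binning, metric MDS embeddings |
| `symperc.augment` | Three-stage late fusion: linear discriminant on base features + one on symmetry scores + a stacking classifier on their posteriors, with leak-free out-of-fold stacking and an outer holdout |
| `symperc.netprobe` | Unit-ablation importance, symmetry modulation index with bootstrap, Gabor spatial-frequency modulation index, a trainable toy network |
| `symperc.cli` | `symperc` command-line pipeline with deterministic, manifest-stamped outputs |

The symmetry score of an image `A` about an axis is
`1 - sum|A - R| / sum(A + R)` where `R` is the reflection of `A` about that
axis: 1 for a pixel-exact mirror-symmetric image, 0 when image and reflection
share no support.

## CLI

All stages are deterministic for a fixed `--seed`; reruns produce
byte-identical outputs. Each stage writes a `run_manifest.json` with input
hashes, parameters and timings.

```sh
# 49 two-part objects (7 parts, 140-px canvas) as PNGs + manifest.csv
symperc stimuli --n-parts 7 --canvas 140 --seed 1 --out stim/

# 8-axis symmetry scores per image
symperc symmetry --images stim/ --n-axes 8 --out scores.csv

# fit weighted component distances to an observed pair table
symperc fit --features features.csv --pairs pairs.csv --pca-dim 0 --seed 1 --out fit.json

# residual table + covariate correlations
symperc residuals --fit fit.json --features features.csv --pairs pairs.csv \
    --covariates pair_symmetry,area_ratio --out residuals.csv

# late-fusion benchmark over categories
symperc augment --features features.csv --symmetry scores.csv --labels labels.csv \
    --folds 10 --holdout 0.2 --seed 1 --out report.csv

# train a toy network on a stimulus set and probe its units
symperc probe --stimuli stim/ --n-units 128 --n-boot 10000 --seed 1 --out probe/
```

Exit codes: 0 success, 2 invalid parameter/config, 3 missing input.

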