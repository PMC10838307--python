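# senodetect

Senescence detection from nuclear morphometry: shape-feature extraction,
tree/forest senescence classifiers with consensus voting, drug-screen
B-score normalization with hit calling, and a cell/tissue senescence
score (CSS/TSS) for histology. A synthetic-data generator stands in for
microscopy data so every stage is testable end-to-end.

## Layout

| Module | What it does |
| --- | --- |
| `senodetect.featuresets` | The three feature schemas: `core7`, `extended17` (17 open-source-style descriptors), `tissue6` |
| `senodetect.features` | Feature extraction from label masks, simple threshold segmentation, acquisition QC (edge/diameter/intensity) |
| `senodetect.synthdata` | Perturbed-ellipse nucleus masks with analytic ground truth, two-population feature tables, screen plates with positional artifacts and spiked actives/toxics, tissue tables with marker-correlated morphology |
| `senodetect.classify` | Training-set construction (assumption- or marker-based labeling), cost-complexity-pruned trees, random forests with vote-fraction probabilities, equal-weight consensus voting, per-well summaries |
| `senodetect.metrics` | Confusion counts, accuracy/precision/recall/F1 (undefined ratios flagged, never zeroed), ROC/PR + AUC, Pearson correlation, two-sample K–S distance |
| `senodetect.screen` | Toxicity exclusion (counts < 40% of positive-control mean), two-way median-polish B-scores, hit calling (B > 15 in ≥ 2 replicates), between-line selectivity classes |
| `senodetect.tissue` | Marker status from DAB intensity (> 0.2), ideal normal/senescent reference derivation (all negatives / top-100 positives), per-cell CSS, per-sample TSS (% of cells with CSS in [1, 5]), sample QC |
| `senodetect.io` / `config` / `cli` | Table dialects (`incarta_like`, `cellprofiler_like`, `qupath_like`, `native`), run configuration with every threshold defaulted, and the CLI |

## CLI

Every command writes its outputs plus a `manifest.json` (stages, inputs,
config hash, version) under `--out`, and is deterministic under `--seed`.

```sh
# synthetic inputs
senodetect simulate --kind population --n-cells 20000 --senescent-fraction 0.0 --seed 1 --out run/
senodetect simulate --kind plates --seed 1 --out run/
senodetect simulate --kind tissue --n-cells 20000 --senescent-fraction 0.3 --seed 1 --out run/

# features from a mask
senodetect extract --mask run/mask.tif --feature-set extended17 --out run/

# train / predict / evaluate
senodetect train --normal normal.csv --senescent senescent.csv --kind forest --seed 0 --out run/
senodetect predict --model run/model_forest.joblib --table cells.csv --well-column well --out run/
senodetect evaluate --predictions run/predictions.csv --out run/

# screens and tissue scoring
senodetect screen --plates run/plates.csv --out run/
senodetect tissue-score --table run/tissue.csv --reference run/ref.json --out run/
```

Thresholds (training-set size, holdout fractions, probability cutoff,
toxicity fraction, B-score threshold, replicate rule, DAB threshold,
circularity filter, minimum cells per sample, CSS window, pixel size)
all live in `senodetect.config.RunConfig` and can be overridden with a
flat YAML file passed as `--config`.

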