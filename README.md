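# skinsens

A QSAR pipeline for predicting human skin sensitization from chemical
structure, built for the kind of data produced by human predictive patch
tests (repeat insult patch tests and maximization tests): small, imbalanced
compound tables with weight-of-evidence outcome labels, salt/mixture/
duplicate pathologies, and noisy dose-per-skin-area potency values.

It is aimed at computational toxicologists who need hazard (sensitizer vs.
non-sensitizer) and potency (GHS NC / 1B / 1A) calls with honest reliability
bounds — calibrated decision thresholds, applicability-domain gating, and
atom-level rationale for each prediction.

## What it does

* **Curation** — structure standardization (counterion stripping,
  neutralization, chemotype normalization, canonical SMILES), rejection of
  mixtures/inorganics/macromolecules, and biological deduplication: records
  of the same structure with concordant outcomes collapse to one, records
  with conflicting outcomes are removed. Binary, three-class, and continuous
  (median → log10 dose) datasets are assembled per outcome scheme, and every
  drop is logged.
* **Models** — random forest, LightGBM, and RBF-SVM classifiers over
  2048-bit ECFP4 fingerprints, MACCS keys, or a 2D physicochemical
  descriptor block; variance filtering, optional recursive feature
  elimination and fold-isolated min–max scaling for descriptors; Bayesian
  hyperparameter search (Gaussian-process surrogate, expected improvement)
  whose trial 0 is always the default configuration.
* **Validation** — 5-fold *external* cross-validation: selection, scaling,
  tuning, the applicability domain and the model are all fitted per fold on
  the 80% split. Metrics follow the standard confusion-matrix definitions,

  SE = TP/(TP+FN), SP = TN/(TN+FP), CCR = (SE+SP)/2,
  PPV = TP/(TP+FP), NPV = TN/(TN+FN),

  macro-averaged one-vs-rest for multiclass, with zero-denominator values
  reported as undefined rather than zero. Y-randomization (label-shuffled
  re-runs) guards against chance correlation.
* **Calibration** — threshold moving: the binary decision cutoff is the
  probability maximizing the geometric mean √(SE·SP) on pooled out-of-fold
  predictions, an exact scan over observed probabilities.
* **Applicability domain** — a query is in-domain iff its Euclidean distance
  to the nearest training compound is ≤ d̄ + Z·s, where d̄ and s summarize
  within-training nearest-neighbor distances and Z defaults to 0.5; metrics
  are reported over in-domain compounds together with coverage.
* **Interpretation** — exactly additive Shapley-style feature attributions
  (permutation sampling), and per-atom fragment-contribution maps: an atom's
  weight is the drop in predicted sensitization probability when the
  fingerprint bits whose circular environments contain that atom are zeroed
  (green = drives sensitization, purple = protective).
* **Landscapes** — ROGI activity-landscape roughness
  (ROGI = 2∫₀¹ (σ(0) − σ(t)) dt under progressive complete-linkage
  coarse-graining), metric MDS projections with interpolated activity
  surfaces, and UMAP chemical-space grouping.
* **Synthetic data** — a generator producing alert-driven chemistry
  (aldehyde → strong sensitizer; sulfonamide, 1,2-diol → weak) with
  configurable imbalance, label noise, salts, mixtures, duplicates, and
  per-class log-normal doses, plus a ground-truth ledger, so the entire
  pipeline is testable offline.

## Worked example

```sh
$ skinsens simulate --n 400 --seed 7 --out raw.csv
wrote 400 entries -> raw.csv
$ skinsens curate --input raw.csv --task binary --scheme WES --out curated.csv --log-out drops.csv
curated 356 compounds (44 logged drops, 0 unreadable rows)
$ skinsens crossvalidate --input curated.csv --features ecfp4 \
    --algorithm random_forest --seed 7 --out cv.json
CCR=0.916 SE=0.984 SP=0.848 coverage=64.3% PT=0.59
```

The 400 raw entries lose 44 to curation (injected mixtures, discordant
duplicates, merged concordant duplicates, missing outcomes). External
cross-validation of the fingerprint random forest then recovers the
structural-alert signal: balanced accuracy (CCR) 0.92 with sensitivity 0.98
and specificity 0.85 over the 64% of out-of-fold compounds inside the
applicability domain, at a calibrated threshold of 0.59 rather than 0.5.

Train a reusable model and score new structures:

```sh
$ skinsens train --input curated.csv --features ecfp4 --seed 7 --bundle-out model
saved bundle to model (pooled CCR=0.916, PT=0.59)
$ printf 'CCCCCC=O\nCCCCO\nnot_a_smiles\n' > query.smi
$ skinsens predict --bundle model --smiles query.smi --out predictions.csv
$ cat predictions.csv
smiles,std_smiles,status,prob,call,ad_distance,in_ad
CCCCCC=O,CCCCCC=O,ok,0.98,1.0,0.0,True
CCCCO,CCCCO,ok,0.05,0.0,0.0,True
not_a_smiles,,error:unparsable,,,,False
```

Hexanal (an aldehyde, i.e. a direct-acting electrophile) is called a
sensitizer at probability 0.98; butanol is cleanly negative; the unparsable
row is reported per-row without aborting the batch. `skinsens interpret`
writes the per-atom contribution weights and an SVG map for any compound.

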