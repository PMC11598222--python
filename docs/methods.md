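# Methods

## Problem and data model

Human predictive patch tests (HPPT: repeat insult patch tests and
maximization tests) yield the most relevant evidence on whether a chemical
causes allergic contact dermatitis, but the resulting compilations are
small (a few hundred compounds per outcome scheme), heavily imbalanced
toward sensitizers (roughly 3–4 sensitizers per non-sensitizer; weak 1B
sensitizers roughly three times as abundant as either other potency class),
and dirty: salt forms, two-fragment mixtures, exact duplicates with
concordant or conflicting outcomes, and dose-per-skin-area (DSA) values
with large per-compound spread. The package models this setting end to
end: hazard (binary), GHS potency (NC/1B/1A), and continuous log-dose
endpoints, each per weight-of-evidence scheme (MLLP, MSPE, WoE, WES).

## Curation

Standardization keeps a single parent fragment when all co-fragments are
recognized counterions or solvates (any carbon-free fragment, plus a small
dictionary of organic counterions: acetate, formate, oxalate,
trifluoroacetate, mesylate, tosylate, tartrate, citrate); two substantial
organic fragments are a mixture and are rejected, as are carbon-free
structures and organics above a configurable 100-heavy-atom cap (the cap
excludes polymers while keeping every plausible patch-test chemical).
Charges are neutralized where valence-legal (quaternary nitrogens stay
charged) and the canonical SMILES of the toolkit, stereo preserved, is the
identity for deduplication. Standardization is idempotent; unparsable input
is a logged rejection, never an exception.

Duplicate concordance is judged at the level the task needs: for the binary
task 1A and 1B agree (both hazards); for the multiclass task they conflict.
Discordant groups are removed entirely. Continuous endpoints take the
median over a structure's entries before the base-10 log; non-positive
doses are dropped and logged. Every assembly op conserves records:
input count = kept + logged.

## Features and selection

* ECFP4: 2048-bit Morgan radius-2 fingerprints — also the substrate for
  atom-level interpretation, so bit identity is never destroyed by
  supervised selection.
* MACCS: 167 positions, index 0 unused (the common convention).
* Continuous descriptors: the full RDKit 2D physicochemical descriptor
  block (~210 descriptors); descriptors non-finite for any compound are
  dropped and recorded.

Unsupervised selection removes features with variance ≤ 0.01 (population
variance, ddof=0 — the convention of the standard variance-threshold
filter, and the one consistent with p(1−p) for binary bits). Supervised
selection (descriptors only) is recursive feature elimination: a small
random forest ranks surviving features by impurity importance and the
lowest 10% of the remaining set is dropped per round until the target count
(default: half the post-variance features). Min–max scaling applies to
descriptors only, is fitted per training fold, maps constant features to 0,
and never clips external rows — out-of-range values are information, not
errors.

## Models, tuning, external cross-validation

Random forest, LightGBM and RBF-SVM (with probability outputs) are trained
on the processed training matrix. Hyperparameter search maximizes mean
3-fold inner-CV CCR within the training split, over conventional spaces
(forest: 100–1000 trees, depth 3–30; boosting: 15–255 leaves, learning
rate 10⁻³–0.3, 100–1000 rounds; SVM: C 10⁻²–10³, γ 10⁻⁴–10, log-scaled
where spans are multiplicative). The optimizer is Bayesian: a Matérn-5/2
Gaussian-process surrogate on the unit-cube encoding with
expected-improvement acquisition over random candidates, seeded and fully
reproducible. Trial 0 always evaluates the default configuration, so the
returned setting never scores below it; with one trial the defaults are
returned unchanged.

Validation is 5-fold *external* cross-validation with stratified folds
(stratification stabilizes folds at n ≈ 150–400 under heavy imbalance):
everything downstream of featurization — undersampling, selection, scaling,
tuning, model, applicability domain — sees only the 80% split. Out-of-fold
probabilities are pooled; one probability threshold is selected on the pool
(so a model carries exactly one PT); headline metrics cover in-domain
out-of-fold compounds, with coverage the in-domain percentage. Multiclass
training folds are rebalanced by randomly undersampling the majority class
to the size of the second largest; minority members are never touched.
Y-randomization repeats the whole procedure on label-shuffled copies with
independently derived seeds.

Undefined metrics (zero denominators) propagate as undefined and are
excluded from macro averages — never silently reported as 0.

## Threshold moving

Imbalanced training depresses minority-class probabilities, so the 0.5
cutoff is replaced by the threshold maximizing √(SE·SP) on held-out
predictions. Because SE and SP only change at observed probabilities, the
scan over observed unique values (with 0.5 always evaluated for reference)
is exact and dominates any fixed grid. The selected threshold is the
smallest observed maximizer — ties resolve toward sensitivity, the
costlier error direction in sensitization screening. The calls induced by
0.5 always coincide with an observed candidate's (or call nothing
positive), so the selected threshold attains the global maximum of the
scan.

## Applicability domain

The AD is the Tropsha-school nearest-neighbor construction: over the
training fold, each compound's Euclidean distance to its nearest other
training compound gives a distribution with mean d̄ and standard deviation
s (ddof=0); the cutoff is D_c = d̄ + Z·s with Z = 0.5 by default. 1-NN
(rather than a k-NN average) defines the distribution; both Z and the
neighbor count are exposed. The AD lives in the model's own input space —
post-selection, post-scaling — because "reliable region" is a property of
what the model consumes. Out-of-domain compounds are still predicted but
flagged, and reported metrics use in-domain compounds only.

## Interpretation

Feature attributions are Shapley values estimated by permutation sampling
against background rows drawn from the AD reference matrix. For each
(background, permutation) pair the marginal contributions telescope to
f(x) − f(b) exactly, so additivity (base + Σφ = model probability) holds to
float precision for every model family and any sampling budget; the
sampling budget controls only the variance of the per-feature split. Only
features differing from the background can carry mass, which bounds the
cost by the number of differing bits rather than the fingerprint width.

Atom contribution maps zero, for each atom, every on-bit whose circular
environment contains that atom (hash-collision bits are zeroed for any
owning atom), and weight the atom by P(full) − P(zeroed). Bits are zeroed
rather than recomputed on a fragment: the question asked is "what does the
model lose when this atom's evidence is removed", not "what would the
model say about a different molecule". Weights are normalized per molecule
by the maximum absolute value, so the map shows relative salience within a
structure; positive (green) atoms drive the sensitizer call, negative
(purple) atoms oppose it. Descriptor models have no bit-to-atom
correspondence and are rejected for maps.

## Activity landscapes

Distances are all-pairs Euclidean on min–max-normalized descriptors,
rescaled to [0, 1] by the maximum. ROGI follows the reference
construction: activities are min–max normalized; complete-linkage
clustering is cut at every merge height (plus 0 and 1); at each threshold
the dataset is coarse-grained to size-weighted cluster means and the
weighted dispersion σ(t) computed; ROGI = 2∫₀¹ (σ(0) − σ(t)) dt by
trapezoidal integration over those thresholds. Constant activity gives 0
exactly; positive affine transforms leave the score unchanged; a dataset
with equal pairwise distances but varying activity is maximally rough and
triggers a warning. Projections use metric MDS (SMACOF, seeded, tight
convergence); activity surfaces use linear barycentric interpolation over
the MDS plane, which passes through the data and cannot over/undershoot
inside the convex hull; collinear configurations are rejected.

Chemical-space grouping embeds Morgan radius-2/2048-bit fingerprints
(variance-filtered) with seeded UMAP and groups compounds by DBSCAN on the
embedding, with the radius set by a 90th-percentile k-distance heuristic
and minimum group size 3 (a noise group is allowed). Because UMAP results
depend on row order even when seeded, compounds are canonically sorted
internally before embedding; the partition is therefore invariant to input
order by construction.

## Synthetic data generator

The generator enumerates a scaffold × substituent space (benzenes,
pyridines, cyclohexanes, alkyl chains × inert and alert substituents) in
which potency is determined by structural alerts: aldehydes are strong
sensitizers — the canonical direct-acting electrophile of the skin
sensitization adverse-outcome pathway — while sulfonamides and 1,2-diols,
both moieties with reported sensitization links, are weak. Defaults encode
the study conditions: 400 entries, sensitizer:non-sensitizer ≈ 3:1, weak ≈
3× strong, 5% label noise, 5% salts, 5% exact duplicates (half of which
receive deliberately conflicting outcomes), 3% two-fragment mixtures, 3%
scheme-wise "unavailable" outcomes, and per-class log₁₀-dose normals
(strong 0.5, weak 2.0, NC 3.5 log µg/cm², sd 0.4) with 30% of compounds
expanded to 2–5 replicate entries at 3× spread, reproducing the wide
per-compound interquartile ranges of real dose data. Every injection is
recorded in a ground-truth ledger so curation can be reconciled
count-for-count.

What the generator does not emulate: real HPPT chemistry distributions
beyond class ratios and noise structure — no vehicle effects, no potency
gradations within an alert class, no correlation between structure and
which scheme reports an outcome. Passing tests therefore demonstrate that
the pipeline recovers a recoverable structure-activity signal under
realistic data pathologies, not that any particular real-data accuracy
will be reached.

## Numerical choices and limitations

* Seeds: every stochastic step takes an explicit seed; multi-round
  procedures derive child seeds via seed sequences (kept below 2³¹).
  Identical configuration implies byte-identical prediction tables.
* Problem sizes: tests and the acceptance script run the full pipeline at
  n = 400 compounds with 5 folds and default (trial-0) hyperparameters,
  sizes at which the alert signal is comfortably recoverable while the
  whole analysis completes in seconds.
* SVM probabilities come from the estimator's internal Platt scaling and
  are therefore only approximately consistent with its decision function;
  threshold moving operates on whatever probabilities the model emits.
* The Bayesian optimizer evaluates a modest number of trials and makes no
  claim of global optimality; its contract is monotone improvement over
  the defaults under a fixed seed.
* Continuous *prediction* is deliberately out of scope: per-compound dose
  variability makes regression on these endpoints unreliable, so the
  continuous datasets feed the landscape analysis only.
* Atom maps inherit fingerprint hash collisions: a bit shared by unrelated
  substructures distributes its influence to every owning atom.
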