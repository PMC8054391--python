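# Methods

This note documents the models, conventions and design choices behind
`modelkiln`, in the spirit of a statistical package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The pipeline model

A model build is a fixed stage sequence:

    read → normalize → annotate → descriptors → scale → fit → cross-validate → report

and a prediction re-runs the *same code* for the shared front half
(read → normalize → descriptors → scale) with the states stored at build
time. This code-sharing is the central consistency guarantee: the
descriptor row of a given molecule is bit-identical whether produced
during training or prediction, so a published model can never drift from
its training pre-processing. Per-molecule failures at any stage (parse
errors, missing or unparseable annotations, unknown elements, adapter
exceptions) flag the molecule and continue; only file-level problems and
degenerate series (fewer than two usable compounds, an empty descriptor
matrix) abort.

## Structures and descriptors

Structures are represented as element/charge lists plus a bond list — a
topological graph, without coordinates or perception chemistry. The SDF
layer supports V2000 connection tables (V3000 entries are flagged failed
with an explicit reason); atom and bond indices are 0-based internally and
converted to the file format's 1-based convention at the boundary.
Fragment stripping (`largest_fragment`) keeps the connected component with
the most atoms, breaking ties by bond count and then lowest first-atom
index. External normalization pipelines and toolkit descriptor sets
(e.g. RDKit properties or fingerprints) plug in through adapter
registries behind the same interfaces; the registry lets a fingerprint
adapter declare Tanimoto rather than Euclidean similarity for the
neighbour search.

The built-in `composition` descriptor set computes, per molecule:
heavy-atom count, bond count, cyclomatic ring count
(bonds − atoms + connected components), molecular weight from a fixed
atomic-mass table (IUPAC 2021 abridged values), and per-element counts
over {C, N, O, S, P, F, Cl, Br, I} — 13 columns. It exists so the entire
framework is testable with zero chemistry-toolkit dependencies; it is not
intended to be a competitive QSAR descriptor set.

Chunked computation (`compute.n_chunks`) splits the series into
contiguous sub-series computed independently and reassembled in input
order. It is strictly a throughput contract: the matrix is identical for
any chunk count, which the tests check for 1–8 chunks. The descriptor
cache is keyed by a digest of the input file *bytes* plus every setting
that influences the matrix (normalization, descriptor method, annotation
settings), so copied files hit and any settings change invalidates;
corrupt cache entries degrade to a recomputation with a warning. The
cache lives in the `dev` folder because published versions are read-only.

Autoscaling standardizes each training column to mean 0 and unit sample
variance (ddof = 1); zero-variance columns get scale 1 and become
centered zeros. Prediction-time scaling always reuses the stored training
centers/scales.

## Learners and conformal uncertainty

The method menu is RF and SVM (scikit-learn), PLS (regression only), and
GBM (xgboost, optional at runtime — its absence shrinks the menu with a
warning rather than failing). All estimators are seeded from the
blueprint; the estimator artifact is serialized with a manifest recording
method, hyperparameters, seed, conformal variant and library versions.
A pass-through hyperparameter grid (`tune.grid`) can be evaluated by
internal cross-validation; it is off by default.

The uncertainty layer is an inductive (split) conformal predictor with a
default calibration fraction of 0.30 held out of the training rows by a
seeded split (stratified for binary endpoints). Choices:

* **Regression nonconformity** is the unnormalized absolute residual,
  giving constant-width intervals; the half-width at confidence c is the
  ⌈c·(n_cal+1)⌉-th smallest calibration residual, saturating at the
  largest residual as c → 1. Difficulty-normalized intervals are an
  extension point, not the default.
* **Classification** is Mondrian (class-conditional): per class c the
  calibration scores are 1 − P(c|x) over calibration members of class c,
  and a query's p-value is the smoothed rank (count of calibration scores
  ≥ the query score, plus one, over n_c + 1). The prediction set contains
  every class with p > 1 − confidence; the four-way outcome labels
  (positive, negative, inconclusive type I = both classes, type II =
  neither) are a direct reading of that set.
* A calibration set below 10 rows is refused outright — conformal
  quantiles from fewer points are meaningless at the confidences used.
* Cross-validation re-splits and re-calibrates inside every fold, so the
  reported conformal statistics are honest out-of-fold measurements.

The conformal guarantee is *marginal*: coverage averages over calibration
draws as well as queries. The validity tests therefore use a large
calibration set (half of 4 000 fit rows) so the conditional coverage of
one fixed calibration draw concentrates tightly enough to compare against
the requested confidence with binomial slack on 2 000 queries.

## Quality statistics conventions

* r² and q² are the determination coefficient 1 − SS_res/SS_tot on fitted
  and cross-validated predictions respectively; with a constant
  experimental vector they are reported as an explicit `undefined` marker.
* MCC with a zero factor in its denominator is reported as 0.
* Conformal *accuracy* divides correct conclusive predictions by the
  total sample count, so inconclusive predictions count against accuracy.
* Conformal *coverage* for classification counts the true class being
  inside the prediction set, so the both-classes set always covers.

These conventions are written into every persisted quality report
(`model-results.yaml`), which stores full-precision values plus
display-rounded copies and round-trips byte-identically.

## Chemical space and applicability domain

The space model is a k = 2 (configurable) PCA of the scaled training
matrix via SVD, with deterministic component signs (largest-magnitude
loading positive) so scores are reproducible across platforms. Queries
are centered with the *training* means and projected on the stored
loadings — never refit. DModX follows the SIMCA convention:

    DModX_i = sqrt( Σ_j e_ij² / (M − k) ) / s0

with e the reconstruction residual and s0 the pooled training residual
standard deviation over (M − k)(n − k − 1) degrees of freedom, so an
average training compound scores near 1 and values well above 1 flag
structures outside the training chemical space. A degenerate space with
zero pooled residual maps zero-residual queries to 0 and anything else to
infinity. If a descriptor set has fewer than k + 1 columns, the build
caps k at M − 1 so DModX keeps at least one residual dimension.
Neighbour retrieval is Euclidean on the scaled descriptors with ties
broken by training order.

## Governance choices

* Model folders: `<repo>/<name>/{dev, ver000001, …}`, zero-padded for
  lexical sort. Publishing copies dev wholesale and strips write
  permissions; the repository API additionally refuses writes to
  published versions regardless of filesystem privileges.
* Unique IDs are ten uppercase ASCII letters drawn from a cryptographic
  source (an injectable RNG keeps tests deterministic); they distinguish
  same-named models across repositories and stamp every prediction.
* Archives (`.mkiln`) are gzip tarballs of the whole model folder plus a
  manifest recording framework version, unique ID and per-version library
  manifests. Import compares recorded library versions against the
  current environment and warns on mismatch — predictions are guaranteed
  identical only when versions match, so the mismatch is surfaced, never
  hidden, and never blocks the install.
* Executing model-embedded code is a real security decision: `custom.py`
  hooks run only when the repository sets `allow_model_code`, an import
  carrying non-template custom code prints a prominent notice, and hooks
  replace whole stages (wrap a default to insert behavior). A raising
  hook aborts the run with a hook-tagged error.
* Duplicate structures in a training series are *not* deduplicated; the
  run report lists duplicate groups so the modeller can decide.
* Predictions persist in `<repo>/.predictions/` until actively deleted;
  each resolves its generating model by unique ID, or to an explicit
  "model deleted" tombstone.

## Ensembles

Member point predictions form the feature matrix (one column per member,
a compound failed by any member fails the ensemble row with provenance).
Majority voting applies to binary endpoints with an exact tie declared
inconclusive — never broken by chance; mean combination sorts the member
values before summing so the result is bit-exactly invariant to member
order. The `meta` combination trains a regular estimator (with optional
conformal layer and cross-validation) on the member matrix. Member
uncertainties (intervals, conformal outcome labels) are reported verbatim
next to the combined value; propagating member errors into a combined
uncertainty is deliberately out of scope.

## The synthetic series generator

Test and demonstration data come from a deterministic generator: random
linear/branched/ring C–N–O graphs (5–14 atoms, single bonds, valences
C ≤ 4, N ≤ 3, O ≤ 2, at most one ring closure) whose activity is by
construction a linear function of the composition descriptors plus
Gaussian noise; binary endpoints threshold the latent at its median by
default, giving balanced classes. Default coefficients weight heavy-atom
count (0.25/atom), ring count (1.0/ring), nitrogen (0.6) and oxygen
(−0.8) so the signal spans several descriptor columns; activity values
are written with six decimals, making the same spec byte-identical every
time. A corruption mode plants parse errors (mangled counts line,
truncated block) and missing annotations at recorded indices for the
error-handling tests.

What the generator does *not* emulate: realistic chemistry (tautomers,
stereochemistry, charge states), realistic descriptor correlation
structure, assay noise heteroscedasticity, or activity cliffs. Passing
tests therefore demonstrate that the machinery is correct — parsing,
matrix construction, conformal calibration arithmetic, versioning,
reproducibility — not that any particular descriptor/learner combination
is adequate for a real endpoint.

## Problem sizes

The test suite and acceptance script use series of 60–200 compounds,
2 000-query Monte-Carlo checks for conformal validity, and 1 000 random
tables for the statistics oracles — sizes at which every quantity checked
is statistically meaningful while a full run stays in the tens of
seconds.

## Known limitations

* Only binary qualitative endpoints; no multiclass support.
* Conformal intervals are constant-width (unnormalized residuals).
* The composition descriptor set ignores bond orders beyond counting.
* No concurrent-access locking on the repository; one writer at a time.
* The TSV input path has no chemical-space neighbour names beyond row
  labels, and no structure round-trip (there are no structures).
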