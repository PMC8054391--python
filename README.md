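# modelkiln

A reproducible QSAR model-lifecycle framework for computational toxicology
and drug discovery. `modelkiln` builds quantitative structure–activity
(QSAR) models from annotated SDFiles or pre-computed descriptor tables,
quantifies every prediction's uncertainty with inductive conformal methods,
and manages the resulting models as versioned, documented, exportable
self-contained folders — so that a model built on one machine gives
byte-identical predictions on another, years later, with full provenance.

It is aimed at modellers who need their QSAR models to be *production
artifacts*: auditable (unique ID watermarks, persistent prediction store,
auto-completed documentation), portable (single-file export/import with
library-version manifests), and statistically honest (conformal prediction
regions at a user-chosen confidence, applicability-domain diagnostics).

## The methods at the core

**Model building.** An annotated series is read from an SDFile (V2000),
normalized (largest-fragment by default), turned into a descriptor matrix
X (a built-in composition set, or any registered toolkit adapter),
autoscaled, and fitted with RF, SVM, PLS or gradient-boosted trees.
Predictive quality is estimated by k-fold cross-validation (default k = 5).

**Quality statistics.** For binary endpoints: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), and the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

For continuous endpoints: SDEC/SDEP = √(Σ(y_exp − y_pred)²/n) over fitted
and cross-validated predictions respectively, and r²/q² = 1 − SS_res/SS_tot.

**Conformal uncertainty.** An inductive (split) conformal layer holds out a
calibration fraction of the training set. For regression, nonconformity is
the absolute residual α_i = |y_i − ŷ_i|; the interval at confidence c is
ŷ ± the ⌈c(n_cal+1)⌉-th smallest α. For binary endpoints a Mondrian
(class-conditional) predictor computes per-class p-values from
α = 1 − P(class|x); the prediction set {c : p_c > 1 − confidence} maps to
four outcomes: positive {1}, negative {0}, inconclusive type I {0,1}, and
inconclusive type II (empty set). Coverage, conformal accuracy and mean
interval width are reported alongside the classical statistics.

**Applicability domain.** A 2-component PCA of the scaled training matrix
gives the chemical-space scores plot; query compounds are projected with
the stored loadings and scored by DModX — the root-mean-square
reconstruction residual over the M−k discarded dimensions, normalized by
the pooled training residual scale s0 — plus a list of nearest training
neighbours with their annotations.

**Governance.** Models live in a repository as folders with a mutable
`dev` version and immutable published versions 1, 2, …; each model carries
a unique ID of ten uppercase ASCII letters stamped on every prediction.
Ensembles use other models' predictions as input features (majority /
mean / median / meta-learner combination). Per-model code overrides
(`custom.py` hooks) can replace pipeline stages for one model only and
travel with exports — they execute only when the repository explicitly
enables model code.

## Worked example

```bash
modelkiln -r repo manage fixtures -n 60 --seed 46 --noise-sd 0.3 -o train.sdf
modelkiln -r repo manage new -e caco2
modelkiln -r repo build -e caco2 -f train.sdf --param annotation.field=activity
modelkiln -r repo manage publish -e caco2
modelkiln -r repo predict -e caco2 -v 1 -f train.sdf -o pred.tsv
```

prints

```
wrote train.sdf and train.truth.tsv
created model caco2 (id XDFWTYKOQE)
built caco2 (dev): n=60, folds=5
  fitting:    {'sdec': 0.471, 'r2': 0.866}
  prediction: {'sdep': 0.834, 'q2': 0.578}
  conformal:  {'coverage': 0.8, 'accuracy': 0.8, 'mean_interval': 2.004}
published caco2 version 1
prediction written to pred.tsv (stored as pred_000001)
```

Reading the numbers: the synthetic 60-compound series has a known linear
activity with noise; the default random-forest fits it with SDEC 0.471
(r² 0.866) and cross-validates at SDEP 0.834 (q² 0.578) over the recorded
5 folds. The conformal layer, asked for 80 % confidence, achieved 80 %
empirical coverage on the out-of-fold predictions with a mean interval
width of 2.0 activity units. The prediction file carries, per compound,
the point estimate, its conformal interval, and its DModX distance to the
training chemical space:

```
name        status  value   y_min   y_max   dmodx
mol_0000    ok      2.125   1.004   3.246   0.333
mol_0001    ok      3.687   2.566   4.808   1.459
```

The same model, exported with `manage export` and imported into any other
repository, reproduces these values byte-for-byte.

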