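"""Estimator construction, inductive conformal prediction, cross-validation.

The machine-learning menu (RF, SVM, PLS, GBM) is backed by scikit-learn and
xgboost; the uncertainty layer is an inductive (split) conformal predictor
written here:

* regression — nonconformity is the unnormalized absolute residual
  ``alpha_i = |y_i - yhat_i|`` on a held-out calibration set; the interval
  at confidence ``c`` is the point prediction plus/minus the
  ``ceil(c * (n_cal + 1))``-th smallest calibration alpha (constant width).
* binary classification — Mondrian (class-conditional) nonconformity
  ``1 - P(class | x)``; the prediction set contains every class whose
  p-value exceeds ``1 - c``.  The set maps to a four-way outcome:
  positive ``{1}``, negative ``{0}``, inconclusive type I ``{0,1}``,
  inconclusive type II (empty set).

Everything is seeded: rebuilding with identical inputs and seeds reproduces
identical predictions.
"""

from __future__ import annotations

import math
import platform
from dataclasses import dataclass, field

import numpy as np
import sklearn
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.svm import SVC, SVR

from .errors import ConfigurationError, FatalError

__all__ = [
    "EstimatorSpec",
    "ConformalSettings",
    "ConformalState",
    "ConformalOutput",
    "CVResult",
    "build_estimator",
    "conformal_calibrate",
    "conformal_predict",
    "cross_validate",
    "available_methods",
    "library_versions",
]

METHODS = ("RF", "SVM", "PLS", "GBM")

OUTCOME_POSITIVE = "positive"
OUTCOME_NEGATIVE = "negative"
OUTCOME_INCONCLUSIVE_I = "inconclusive_I"  # set = {0, 1}
OUTCOME_INCONCLUSIVE_II = "inconclusive_II"  # set = {}


def _xgboost():
    try:
        import xgboost

        return xgboost
    except ImportError:
        return None


def available_methods(task: str = "regression") -> list:
    """The method menu usable in this environment for the given task."""
    menu = ["RF", "SVM"]
    if task == "regression":
        menu.append("PLS")
    if _xgboost() is not None:
        menu.append("GBM")
    return menu


def library_versions() -> dict:
    """Library versions recorded in every estimator manifest."""
    versions = {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scikit-learn": sklearn.__version__,
    }
    xgb = _xgboost()
    if xgb is not None:
        versions["xgboost"] = xgb.__version__
    return versions


@dataclass
class EstimatorSpec:
    method: str = "RF"
    task: str = "regression"  # "regression" | "classification"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 46


@dataclass
class ConformalSettings:
    enabled: bool = True
    confidence: float = 0.8
    calibration_fraction: float = 0.3
    seed: int = 46


@dataclass
class ConformalState:
    """Calibration alphas; for classification one sorted array per class."""

    task: str
    alphas: np.ndarray | None = None  # regression
    class_alphas: dict | None = None  # classification: {0: array, 1: array}
    variant: str = "inductive"  # classification adds "mondrian"


@dataclass
class ConformalOutput:
    """Per-compound conformal results.

    Regression: ``point``, ``y_min``, ``y_max`` arrays with
    ``y_min <= point <= y_max``.  Classification: ``point`` (argmax class),
    ``p_values`` (n x 2), ``sets`` (tuples over {0,1}) and the four-way
    ``outcomes`` labels.
    """

    task: str
    point: np.ndarray
    y_min: np.ndarray | None = None
    y_max: np.ndarray | None = None
    p_values: np.ndarray | None = None
    sets: list | None = None
    outcomes: list | None = None


class _PLSWrapper:
    """PLS regression with a flat predict(), sklearn-style."""

    def __init__(self, n_components=2):
        self.n_components = n_components
        self._pls = None

    def fit(self, X, y):
        k = min(self.n_components, X.shape[1], max(X.shape[0] - 1, 1))
        self._pls = PLSRegression(n_components=k, scale=False)
        self._pls.fit(X, y)
        return self

    def predict(self, X):
        return np.asarray(self._pls.predict(X)).ravel()


def _make_estimator(spec: EstimatorSpec):
    hp = dict(spec.hyperparameters)
    if spec.method == "RF":
        cls = RandomForestClassifier if spec.task == "classification" else RandomForestRegressor
        hp.setdefault("n_estimators", 100)
        return cls(random_state=spec.seed, **hp)
    if spec.method == "SVM":
        if spec.task == "classification":
            return SVC(probability=True, random_state=spec.seed, **hp)
        return SVR(**hp)
    if spec.method == "PLS":
        if spec.task == "classification":
            raise ConfigurationError("PLS supports regression only")
        return _PLSWrapper(n_components=hp.get("n_components", 2))
    if spec.method == "GBM":
        xgb = _xgboost()
        if xgb is None:
            raise ConfigurationError(
                "GBM requires xgboost, which is not installed; "
                f"available methods: {available_methods(spec.task)}"
            )
        cls = xgb.XGBClassifier if spec.task == "classification" else xgb.XGBRegressor
        hp.setdefault("n_estimators", 100)
        return cls(random_state=spec.seed, verbosity=0, **hp)
    raise ConfigurationError(
        f"unknown method {spec.method!r}; choose one of {list(METHODS)}"
    )


def build_estimator(X: np.ndarray, y: np.ndarray, spec: EstimatorSpec):
    """Fit an estimator on (scaled) X and y per the spec. Fully seeded."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if spec.task == "classification":
        y = y.astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ConfigurationError("classification endpoints must be binary 0/1")
    est = _make_estimator(spec)
    est.fit(X, y)
    return est


def _class_probabilities(estimator, X: np.ndarray) -> np.ndarray:
    """P(class 0), P(class 1) per row, robust to single-class training."""
    proba = estimator.predict_proba(X)
    classes = list(getattr(estimator, "classes_", [0, 1]))
    out = np.zeros((X.shape[0], 2))
    for j, c in enumerate(classes):
        out[:, int(c)] = proba[:, j]
    return out


def conformal_calibrate(
    estimator, X_cal: np.ndarray, y_cal: np.ndarray, settings: ConformalSettings,
    task: str = "regression",
) -> ConformalState:
    """Compute calibration nonconformity scores on a held-out set.

    The calibration rows must be disjoint from the rows the estimator was
    trained on — exchangeability is what makes the coverage guarantee hold.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    if len(y_cal) < 10:
        raise FatalError(
            f"calibration too small: {len(y_cal)} rows (need >= 10)", stage="learn"
        )
    if task == "regression":
        alphas = np.sort(np.abs(y_cal - estimator.predict(X_cal)))
        return ConformalState(task=task, alphas=alphas)
    proba = _class_probabilities(estimator, X_cal)
    class_alphas = {}
    for c in (0, 1):
        members = y_cal.astype(int) == c
        class_alphas[c] = np.sort(1.0 - proba[members, c])
    return ConformalState(task=task, class_alphas=class_alphas, variant="mondrian")


def _interval_half_width(alphas: np.ndarray, confidence: float) -> float:
    """The ceil(c*(n+1))-th smallest alpha; saturates at max alpha as c -> 1."""
    n = len(alphas)
    k = math.ceil(confidence * (n + 1) - 1e-12)
    k = min(max(k, 1), n)
    return float(alphas[k - 1])


def conformal_predict(
    estimator, state: ConformalState, X: np.ndarray, confidence: float
) -> ConformalOutput:
    """Point predictions plus conformal region at the given confidence."""
    if not 0.0 < confidence < 1.0:
        raise ConfigurationError(f"confidence must be in (0,1), got {confidence}")
    X = np.asarray(X, dtype=float)
    if state.task == "regression":
        point = np.asarray(estimator.predict(X), dtype=float).ravel()
        hw = _interval_half_width(state.alphas, confidence)
        return ConformalOutput(
            task="regression", point=point, y_min=point - hw, y_max=point + hw
        )

    proba = _class_probabilities(estimator, X)
    point = np.argmax(proba, axis=1).astype(float)
    eps = 1.0 - confidence
    p_values = np.zeros((X.shape[0], 2))
    sets, outcomes = [], []
    for i in range(X.shape[0]):
        included = []
        for c in (0, 1):
            alphas_c = state.class_alphas[c]
            a_query = 1.0 - proba[i, c]
            p = (np.sum(alphas_c >= a_query - 1e-15) + 1) / (len(alphas_c) + 1)
            p_values[i, c] = p
            if p > eps:
                included.append(c)
        included = tuple(included)
        sets.append(included)
        if included == (1,):
            outcomes.append(OUTCOME_POSITIVE)
        elif included == (0,):
            outcomes.append(OUTCOME_NEGATIVE)
        elif included == (0, 1):
            outcomes.append(OUTCOME_INCONCLUSIVE_I)
        else:
            outcomes.append(OUTCOME_INCONCLUSIVE_II)
    return ConformalOutput(
        task="classification",
        point=point,
        p_values=p_values,
        sets=sets,
        outcomes=outcomes,
    )


def fit_conformal(X, y, spec: EstimatorSpec, settings: ConformalSettings):
    """Proper-training/calibration split, fit, calibrate.

    Returns ``(estimator, state)``.  With conformal disabled the estimator
    is fit on all rows and the state is None.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not settings.enabled:
        return build_estimator(X, y, spec), None
    stratify = y.astype(int) if spec.task == "classification" else None
    X_tr, X_cal, y_tr, y_cal = train_test_split(
        X,
        y,
        test_size=settings.calibration_fraction,
        random_state=settings.seed,
        stratify=stratify,
    )
    est = build_estimator(X_tr, y_tr, spec)
    state = conformal_calibrate(est, X_cal, y_cal, settings, task=spec.task)
    return est, state


@dataclass
class CVResult:
    """Out-of-fold predictions: every row predicted exactly once."""

    y_pred: np.ndarray
    fold_assignment: np.ndarray
    folds: int
    conformal: ConformalOutput | None = None


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: EstimatorSpec,
    settings: ConformalSettings | None = None,
    folds: int = 5,
    seed: int = 46,
) -> CVResult:
    """k-fold cross-validation with per-fold conformal recalibration.

    Fold assignment is reproducible from the seed; classification uses
    stratified folds.  The default of five folds is applied by callers that
    leave ``folds`` unset and is recorded in the quality report.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    if folds > n:
        raise FatalError(f"folds ({folds}) exceed series size ({n})", stage="learn")
    if n < 2 * folds:
        raise FatalError(
            f"series too small for {folds}-fold validation: n={n}", stage="learn"
        )
    settings = settings or ConformalSettings(enabled=False)

    if spec.task == "classification":
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y.astype(int))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X)

    y_pred = np.zeros(n)
    assignment = np.zeros(n, dtype=int)
    conf_enabled = settings.enabled
    if conf_enabled:
        if spec.task == "regression":
            y_min = np.zeros(n)
            y_max = np.zeros(n)
        else:
            p_values = np.zeros((n, 2))
            sets_arr: list = [None] * n
            outcomes_arr: list = [None] * n

    for fold_idx, (train_idx, test_idx) in enumerate(split_iter):
        assignment[test_idx] = fold_idx
        est, state = fit_conformal(X[train_idx], y[train_idx], spec, settings)
        if conf_enabled:
            out = conformal_predict(est, state, X[test_idx], settings.confidence)
            y_pred[test_idx] = out.point
            if spec.task == "regression":
                y_min[test_idx] = out.y_min
                y_max[test_idx] = out.y_max
            else:
                p_values[test_idx] = out.p_values
                for local, global_i in enumerate(test_idx):
                    sets_arr[global_i] = out.sets[local]
                    outcomes_arr[global_i] = out.outcomes[local]
        else:
            y_pred[test_idx] = np.asarray(est.predict(X[test_idx])).ravel()

    conformal = None
    if conf_enabled:
        if spec.task == "regression":
            conformal = ConformalOutput(
                task="regression", point=y_pred.copy(), y_min=y_min, y_max=y_max
            )
        else:
            conformal = ConformalOutput(
                task="classification",
                point=y_pred.copy(),
                p_values=p_values,
                sets=sets_arr,
                outcomes=outcomes_arr,
            )
    return CVResult(y_pred=y_pred, fold_assignment=assignment, folds=folds, conformal=conformal)
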