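"""High-level build and predict orchestrations.

``build`` runs the full pipeline — read, normalize, annotate, descriptors,
scale, fit, cross-validate, report — and persists every artifact into the
model's ``dev`` folder, overwriting any previous dev build.  ``predict``
re-runs *exactly the same* pre-processing code with the stored states of a
published version, which is what makes the descriptor row of a molecule
bit-identical between training and prediction.

Per-model code overrides: a model folder may carry ``custom.py`` defining
``hook_normalize`` / ``hook_descriptors`` / ``hook_post_output``.  When the
repository enables model code, these replace the corresponding stage for
this model only and travel with export/import.
"""

from __future__ import annotations

import datetime
import importlib.util
import itertools
import json
import shutil
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from . import __version__ as framework_version
from .chemio import (
    AnnotatedSeries,
    extract_annotations,
    normalize_structure,
    read_sdf,
    read_tsv_table,
)
from .chemspace import SpaceModel, dmodx, fit_space, nearest_training, project
from .descriptors import (
    DescriptorCache,
    DescriptorMatrix,
    ScalerState,
    apply_scaler,
    compute_descriptors,
    fit_scaler,
    series_fingerprint,
)
from .errors import FatalError
from .learners import (
    ConformalSettings,
    EstimatorSpec,
    conformal_predict,
    cross_validate,
    fit_conformal,
    library_versions,
)
from .metrics import (
    QualityReport,
    RegressionPairs,
    classification_stats,
    confusion_from_predictions,
    conformal_stats,
    regression_stats,
    series_stats,
)
from .params import ParameterSet
from .repository import HOOK_FILE, ModelRepository

__all__ = ["build", "predict", "load_overrides", "PredictionRecord", "Hooks"]

_BUILD_ARTIFACTS = (
    "estimator.bin",
    "estimator.manifest",
    "scaler.json",
    "space.json",
    "training.json",
    "training_input.sdf",
    QualityReport.FILENAME,
    "documentation.yml",
    "failures.tsv",
)


@dataclass
class Hooks:
    normalize: object = None
    descriptors: object = None
    post_output: object = None

    def __bool__(self):
        return any((self.normalize, self.descriptors, self.post_output))


def load_overrides(model_folder, allow_model_code: bool = False) -> Hooks:
    """Load per-model stage overrides from the folder's ``custom.py``.

    Hooks present while model code is disabled produce a warning and are
    ignored; an import error is a hook-tagged fatal error.
    """
    hook_path = Path(model_folder) / HOOK_FILE
    if not hook_path.exists():
        return Hooks()
    previous = sys.dont_write_bytecode
    sys.dont_write_bytecode = True  # keep model folders free of __pycache__
    try:
        spec = importlib.util.spec_from_file_location(
            f"modelkiln_hooks_{abs(hash(str(hook_path)))}", hook_path
        )
        module = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(module)
    except Exception as exc:  # noqa: BLE001
        raise FatalError(f"cannot load model hooks from {hook_path}: {exc}", stage="hooks")
    finally:
        sys.dont_write_bytecode = previous
    hooks = Hooks(
        normalize=getattr(module, "hook_normalize", None),
        descriptors=getattr(module, "hook_descriptors", None),
        post_output=getattr(module, "hook_post_output", None),
    )
    if hooks and not allow_model_code:
        warnings.warn(
            f"model folder {model_folder} defines code overrides but the "
            "repository does not set allow_model_code; defaults are used"
        )
        return Hooks()
    return hooks


def _run_hook(func, stage: str, *args):
    try:
        return func(*args)
    except Exception as exc:  # noqa: BLE001
        raise FatalError(f"model hook for stage {stage!r} raised: {exc}", stage="hooks")


# ---------------------------------------------------------------------------
# Shared pre-processing (the build/predict code-sharing guarantee)


def _prepare_records(input_path, params: ParameterSet, hooks: Hooks):
    records = read_sdf(input_path)
    if not records:
        raise FatalError(f"no structures in {input_path}", stage="idata")
    if hooks.normalize is not None:
        records = _run_hook(hooks.normalize, "normalize", records)
    else:
        method = params.get("normalization.method")
        records = [normalize_structure(r, method) for r in records]
    return records


def _compute_matrix(records, params: ParameterSet, hooks: Hooks, cache: DescriptorCache | None,
                    fingerprint: str | None) -> DescriptorMatrix:
    if hooks.descriptors is not None:
        dm = _run_hook(hooks.descriptors, "descriptors", records)
        dm.validate()
        return dm
    if cache is not None and fingerprint is not None:
        hit = cache.get(fingerprint)
        if hit is not None:
            return hit
    dm = compute_descriptors(
        records,
        method=params.get("descriptors.method"),
        n_chunks=params.get("compute.n_chunks"),
    )
    if cache is not None and fingerprint is not None:
        cache.put(fingerprint, dm)
    return dm


def _duplicate_groups(records) -> list:
    """Names of structurally identical ok records (no deduplication is done)."""
    seen: dict = {}
    for rec in records:
        if rec.status != "ok":
            continue
        sig = (tuple(rec.atoms), tuple(sorted(rec.bonds)))
        seen.setdefault(sig, []).append(rec.name)
    return [names for names in seen.values() if len(names) > 1]


# ---------------------------------------------------------------------------
# Hyperparameter tuning (pass-through grid, internal CV; off by default)


def _tune_hyperparameters(X, y, spec: EstimatorSpec, grid: dict, folds: int, seed: int) -> dict:
    if not grid:
        return spec.hyperparameters
    keys = sorted(grid)
    best_score, best_hp = -np.inf, spec.hyperparameters
    for combo in itertools.product(*(grid[k] for k in keys)):
        hp = dict(spec.hyperparameters)
        hp.update(dict(zip(keys, combo)))
        trial = EstimatorSpec(spec.method, spec.task, hp, spec.seed)
        cv = cross_validate(X, y, trial, None, folds=folds, seed=seed)
        if spec.task == "classification":
            score = classification_stats(confusion_from_predictions(y, cv.y_pred))["mcc"]
        else:
            score = regression_stats(RegressionPairs(y, cv.y_pred), "prediction")["q2"]
            score = -np.inf if isinstance(score, str) else score
        if score > best_score:
            best_score, best_hp = score, hp
    return best_hp


# ---------------------------------------------------------------------------
# Build


def build(repo: ModelRepository, model_name: str, input_path, overrides=None) -> QualityReport:
    """Build (or rebuild) the dev version of a model from an input series.

    The input is an annotated SDFile or a TSV of pre-computed descriptors.
    Per-molecule failures accumulate in the report; only stage-level
    problems (unreadable file, empty matrix, too-small series) abort.
    """
    params = ParameterSet.load(repo.version_dir(model_name, "dev"))
    params.apply_overrides(overrides)

    ensemble_members = params.get("ensemble.members")
    if ensemble_members:
        from .ensembles import build_ensemble

        return build_ensemble(repo, model_name, input_path, params)

    params.validate_for_build()
    dev = repo.version_dir(model_name, "dev")
    hooks = load_overrides(dev, repo.allow_model_code)
    input_path = Path(input_path)
    endpoint = params.get("annotation.endpoint_type")
    task = "classification" if endpoint == "qualitative" else "regression"

    # ---- idata: read, normalize, annotate, descriptors
    if input_path.suffix.lower() in (".tsv", ".txt"):
        dm, y = read_tsv_table(input_path, params.get("annotation.field"))
        records = None
        series = None
        y_used = y
        row_ids = dm.row_ids
        failures = list(dm.failures)
        duplicates = []
        if len(y_used) < 2:
            raise FatalError("series too small", stage="idata")
    else:
        records = _prepare_records(input_path, params, hooks)
        series = extract_annotations(
            records,
            params.get("annotation.field"),
            endpoint,
            params.get("annotation.positive_synonyms"),
            params.get("annotation.negative_synonyms"),
        )
        records = series.records
        duplicates = _duplicate_groups(records)
        fingerprint = series_fingerprint(
            input_path.read_bytes(),
            params.get("normalization.method"),
            params.get("descriptors.method"),
            extra=f"annot={params.get('annotation.field')}|{endpoint}",
        )
        cache = None if hooks.descriptors else DescriptorCache(dev / "cache")
        dm = _compute_matrix(records, params, hooks, cache, fingerprint)
        # align y (over annotation-ok records) with descriptor successes
        y_used, row_ids, y_iter = [], [], iter(series.y)
        for rec, ok in zip(records, dm.success_mask):
            if rec.status == "ok":
                yv = next(y_iter)
                if ok:
                    y_used.append(yv)
                    row_ids.append(rec.name)
        y_used = np.asarray(y_used, dtype=float)
        failures = [
            (rec.source_index, rec.name, rec.failure_reason)
            for rec in records
            if rec.status != "ok"
        ]
        for src, nm, reason in dm.failures:
            if all(src != f[0] for f in failures):
                failures.append((src, nm, reason))
        failures.sort(key=lambda f: f[0])
        if len(y_used) < 2:
            raise FatalError("series too small after failures", stage="idata")

    # ---- scale, chemical space
    scaler = fit_scaler(dm.X, params.get("descriptors.scaling"))
    X = apply_scaler(dm.X, scaler)
    # cap components at M-1 so DModX keeps residual dimensions
    k = max(1, min(params.get("chemspace.components"), X.shape[1] - 1))
    space = fit_space(X, k=k)

    # ---- learn
    seed = params.get("learner.seed")
    hp = params.get("learner.hyperparameters")
    spec = EstimatorSpec(params.get("learner.method"), task, hp, seed)
    conf = params.get("conformal")
    settings = ConformalSettings(
        enabled=conf["enabled"],
        confidence=conf["confidence"],
        calibration_fraction=conf["calibration_fraction"],
        seed=conf["seed"],
    )
    spec.hyperparameters = _tune_hyperparameters(
        X, y_used, spec, params.get("tune.grid"), params.get("validation.folds"), seed
    )
    estimator, conformal_state = fit_conformal(X, y_used, spec, settings)
    cv = cross_validate(
        X, y_used, spec, settings,
        folds=params.get("validation.folds"),
        seed=params.get("validation.seed"),
    )

    # ---- metrics
    fitted = np.asarray(estimator.predict(X), dtype=float).ravel()
    if task == "classification":
        fitting = classification_stats(confusion_from_predictions(y_used, fitted))
        prediction = classification_stats(confusion_from_predictions(y_used, cv.y_pred))
    else:
        fitting = regression_stats(RegressionPairs(y_used, fitted), "fitting")
        prediction = regression_stats(RegressionPairs(y_used, cv.y_pred), "prediction")
    conformal_block = (
        conformal_stats(cv.conformal, y_used) if cv.conformal is not None else None
    )
    series_block = series_stats(
        AnnotatedSeries([], y_used, params.get("annotation.field") or "", endpoint)
    )

    train_scores = project(space, X)
    report = QualityReport(
        endpoint_type=endpoint,
        fitting=fitting,
        prediction=prediction,
        conformal=conformal_block,
        series=series_block,
        chemspace={
            "scores": train_scores.tolist(),
            "dmodx": dmodx(space, X).tolist(),
            "annotations": np.asarray(y_used, dtype=float).tolist(),
        },
        folds=cv.folds,
        n_used=len(y_used),
        failures=[list(f) for f in failures],
        duplicates=duplicates,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )

    # ---- persist: previous dev build is fully replaced
    for name in _BUILD_ARTIFACTS:
        target = dev / name
        if target.exists():
            target.unlink()
    params.save(dev / ParameterSet.FILENAME)
    joblib.dump({"estimator": estimator, "conformal_state": conformal_state}, dev / "estimator.bin")
    manifest = {
        "method": spec.method,
        "task": spec.task,
        "hyperparameters": spec.hyperparameters,
        "seed": spec.seed,
        "conformal_variant": "mondrian" if task == "classification" else "inductive",
        "library_versions": library_versions(),
    }
    (dev / "estimator.manifest").write_text(yaml.safe_dump(manifest, sort_keys=True))
    _save_scaler(dev / "scaler.json", scaler)
    space.save(dev / "space.json")
    with open(dev / "training.json", "w") as fh:
        json.dump(
            {
                "X_scaled": X.tolist(),
                "names": dm.names,
                "row_ids": row_ids,
                "y": np.asarray(y_used, dtype=float).tolist(),
            },
            fh,
        )
    if input_path.suffix.lower() not in (".tsv", ".txt"):
        shutil.copyfile(input_path, dev / "training_input.sdf")
    report.save(dev / QualityReport.FILENAME)
    with open(dev / "failures.tsv", "w") as fh:
        for src, nm, reason in failures:
            fh.write(f"{src}\t{nm}\t{reason}\n")
    repo.autofill_documentation(model_name, params, report)
    return report


def _save_scaler(path, scaler: ScalerState) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "method": scaler.method,
                "centers": scaler.centers.tolist(),
                "scales": scaler.scales.tolist(),
            },
            fh,
        )


def _load_scaler(path) -> ScalerState:
    with open(path) as fh:
        d = json.load(fh)
    return ScalerState(
        d["method"], np.asarray(d["centers"], float), np.asarray(d["scales"], float)
    )


# ---------------------------------------------------------------------------
# Prediction


@dataclass
class PredictionRecord:
    """Per-compound prediction results stamped with full model provenance."""

    header: dict  # model_name, unique_id, version, confidence, endpoint_type, timestamp
    compounds: list = field(default_factory=list)
    interpretation: str = ""

    def to_dict(self) -> dict:
        return {
            "header": dict(self.header),
            "compounds": [dict(c) for c in self.compounds],
            "interpretation": self.interpretation,
        }

    def payload_canonical(self) -> bytes:
        """Deterministic serialization for reproducibility comparisons.

        Excludes the wall-clock timestamp; everything else — values,
        intervals, outcomes, model identity — is byte-exact.
        """
        d = self.to_dict()
        d["header"] = {k: v for k, v in d["header"].items() if k != "timestamp"}
        return json.dumps(d, sort_keys=True).encode()

    def to_tsv(self) -> str:
        cols = ["name", "status", "value", "y_min", "y_max", "outcome", "dmodx", "reason"]
        lines = ["\t".join(cols)]
        for c in self.compounds:
            lines.append(
                "\t".join(str(c.get(k, "")) for k in cols)
            )
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".tsv":
            path.write_text(self.to_tsv())
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def predict(
    repo: ModelRepository,
    model_name: str,
    version,
    input_path,
    confidence: float | None = None,
) -> PredictionRecord:
    """Predict an input series with a *published* model version.

    Pre-processing re-uses the identical code path and the stored
    normalization/descriptor/scaler/space states of that version; the
    result is stamped with the model's unique ID and version.  A
    prediction-time confidence overrides the build-time default without
    touching any stored state.
    """
    if version == "dev":
        raise FatalError(
            "the dev version cannot be used for prediction; publish it first",
            stage="apply",
        )
    vdir = repo.version_dir(model_name, version)
    params = ParameterSet.load(vdir)
    hooks = load_overrides(vdir, repo.allow_model_code)

    if params.get("ensemble.members"):
        from .ensembles import predict_ensemble

        return predict_ensemble(repo, model_name, version, input_path, confidence)

    endpoint = params.get("annotation.endpoint_type")
    task = "classification" if endpoint == "qualitative" else "regression"
    confidence = confidence if confidence is not None else params.get("conformal.confidence")

    records = _prepare_records(input_path, params, hooks)
    dm = _compute_matrix(records, params, hooks, cache=None, fingerprint=None)
    scaler = _load_scaler(vdir / "scaler.json")
    X = apply_scaler(dm.X, scaler)
    space = SpaceModel.load(vdir / "space.json")
    xdm = dmodx(space, X)

    bundle = joblib.load(vdir / "estimator.bin")
    estimator, state = bundle["estimator"], bundle["conformal_state"]

    if state is not None:
        out = conformal_predict(estimator, state, X, confidence)
    else:
        out = None
        points = np.asarray(estimator.predict(X), dtype=float).ravel()

    doc = repo.document_model(model_name, version)
    interpretation = str(
        doc.get("General Model information", {}).get("Interpretation", "")
    )

    compounds = []
    row = 0
    for rec, ok in zip(records, dm.success_mask):
        entry = {"name": rec.name, "source_index": rec.source_index}
        if not ok:
            entry["status"] = "failed"
            entry["reason"] = rec.failure_reason or next(
                (f[2] for f in dm.failures if f[0] == rec.source_index), "unknown"
            )
            compounds.append(entry)
            continue
        entry["status"] = "ok"
        entry["dmodx"] = float(xdm[row])
        if out is not None and task == "regression":
            entry["value"] = float(out.point[row])
            entry["y_min"] = float(out.y_min[row])
            entry["y_max"] = float(out.y_max[row])
        elif out is not None:
            entry["value"] = int(out.point[row])
            entry["outcome"] = out.outcomes[row]
            entry["p_values"] = [float(p) for p in out.p_values[row]]
            entry["set"] = list(out.sets[row])
        else:
            entry["value"] = (
                int(points[row]) if task == "classification" else float(points[row])
            )
        if hooks.post_output is not None:
            entry = _run_hook(hooks.post_output, "post-output", entry)
        compounds.append(entry)
        row += 1

    header = {
        "model_name": model_name,
        "unique_id": repo.unique_id(model_name),
        "version": int(version),
        "confidence": float(confidence),
        "endpoint_type": endpoint,
        "framework_version": framework_version,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return PredictionRecord(header=header, compounds=compounds, interpretation=interpretation)


def neighbors(repo: ModelRepository, model_name: str, version, X_query_scaled, n_neighbors=5):
    """Closest training compounds of a version, on its own descriptor space."""
    vdir = repo.version_dir(model_name, version)
    with open(vdir / "training.json") as fh:
        training = json.load(fh)
    return nearest_training(
        np.asarray(training["X_scaled"], float),
        training["row_ids"],
        training["y"],
        X_query_scaled,
        n_neighbors,
    )
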