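"""Ensemble models: models whose inputs are other models' predictions.

An ensemble model lists member ``(name, version)`` pairs in its blueprint;
at build and predict time each member's point predictions form one column
of a matrix used as a sort of "molecular descriptors".  Qualitative
members combine by majority vote (an exact tie is an inconclusive result,
never a coin flip); quantitative members by mean or median; ``meta``
trains a regular estimator on the member matrix.

Member prediction uncertainties are reported verbatim next to the combined
result; no error propagation across members is attempted.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import joblib
import numpy as np
import yaml

from . import __version__ as framework_version
from .chemio import extract_annotations, read_sdf
from .descriptors import DescriptorMatrix, apply_scaler, fit_scaler
from .errors import ConfigurationError, FatalError
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
from .chemio import AnnotatedSeries
from .params import ParameterSet
from .repository import ModelRepository

__all__ = ["validate_members", "ensemble_matrix", "combine", "build_ensemble", "predict_ensemble"]

INCONCLUSIVE = "inconclusive"


def validate_members(repo: ModelRepository, members, endpoint_type: str) -> list:
    """Check the member list: >= 2, published, resolvable, same endpoint."""
    if len(members) < 2:
        raise ConfigurationError("an ensemble needs at least 2 members")
    resolved = []
    for entry in members:
        name, version = entry[0], int(entry[1])
        try:
            vdir = repo.version_dir(name, version)
        except Exception as exc:
            raise FatalError(
                f"ensemble member {name!r} version {version} not found in the "
                f"repository: {exc}",
                stage="learn",
            )
        member_params = ParameterSet.load(vdir)
        ep = member_params.get("annotation.endpoint_type")
        if ep != endpoint_type:
            raise ConfigurationError(
                f"member {name!r} endpoint type {ep!r} does not match the "
                f"ensemble endpoint {endpoint_type!r}"
            )
        resolved.append((name, version))
    return resolved


def ensemble_matrix(repo: ModelRepository, members, input_path, confidence=None):
    """Member point predictions as an n x n_members matrix.

    Column j holds member j's point prediction per compound; a compound
    failed by *any* member is failed in the ensemble row, with the failing
    member recorded.  Returns ``(DescriptorMatrix, member_records)`` where
    the latter keeps each member's full PredictionRecord for reporting.
    """
    from .workflows import predict

    member_records = []
    for name, version in members:
        try:
            record = predict(repo, name, version, input_path, confidence)
        except Exception as exc:
            raise FatalError(
                f"ensemble member {name!r} v{version} cannot predict: {exc}",
                stage="apply",
            )
        member_records.append((name, version, record))

    n = len(member_records[0][2].compounds)
    columns, names = [], []
    failures = {}  # source_index -> (name, reason)
    for name, version, record in member_records:
        col = []
        for c in record.compounds:
            if c["status"] != "ok":
                failures.setdefault(
                    c["source_index"],
                    (c["name"], f"failed by member {name} v{version}: {c.get('reason', '')}"),
                )
                col.append(np.nan)
            else:
                col.append(float(c["value"]))
        columns.append(col)
        names.append(f"{name}_v{version}")

    M = np.asarray(columns, dtype=float).T
    mask = ~np.any(np.isnan(M), axis=1)
    if not mask.any():
        raise FatalError("empty ensemble matrix: every compound failed", stage="idata")
    row_ids = [
        member_records[0][2].compounds[i]["name"] for i in range(n) if mask[i]
    ]
    dm = DescriptorMatrix(
        X=M[mask],
        names=names,
        row_ids=row_ids,
        success_mask=mask,
        failures=[(idx, failures[idx][0], failures[idx][1]) for idx in sorted(failures)],
    )
    dm.validate()
    return dm, member_records


def combine(values, combination: str, endpoint_type: str = "quantitative"):
    """Combine one compound's member predictions into a single result."""
    values = list(values)
    if combination == "majority":
        if endpoint_type != "qualitative":
            raise ConfigurationError("majority voting applies to qualitative endpoints")
        ones = sum(1 for v in values if int(v) == 1)
        zeros = len(values) - ones
        if ones > zeros:
            return 1
        if zeros > ones:
            return 0
        return INCONCLUSIVE
    if combination == "mean":
        # canonical summation order keeps the result permutation invariant
        return float(np.mean(np.sort(np.asarray(values, dtype=float))))
    if combination == "median":
        return float(np.median(values))
    raise ConfigurationError(
        f"unknown combination {combination!r}; choose majority, mean, median or meta"
    )


def _combined_vector(X: np.ndarray, combination: str, endpoint_type: str):
    return [combine(row, combination, endpoint_type) for row in X]


def build_ensemble(repo: ModelRepository, model_name: str, input_path, params: ParameterSet) -> QualityReport:
    """Build the dev version of an ensemble model from an annotated SDFile."""
    endpoint = params.get("annotation.endpoint_type")
    task = "classification" if endpoint == "qualitative" else "regression"
    combination = params.get("ensemble.combination")
    if combination == "majority" and endpoint != "qualitative":
        raise ConfigurationError("majority combination requires a qualitative endpoint")
    members = validate_members(repo, params.get("ensemble.members"), endpoint)
    dev = repo.version_dir(model_name, "dev")

    records = read_sdf(input_path)
    series = extract_annotations(
        records,
        params.get("annotation.field"),
        endpoint,
        params.get("annotation.positive_synonyms"),
        params.get("annotation.negative_synonyms"),
    )
    dm, member_records = ensemble_matrix(repo, members, input_path)

    # align annotations with the ensemble matrix rows
    y_used, y_iter = [], iter(series.y)
    annot_ok = {r.source_index for r in series.records if r.status == "ok"}
    y_by_index = dict(zip(sorted(annot_ok), series.y))
    keep_rows, y_used = [], []
    for row, idx in enumerate(np.nonzero(dm.success_mask)[0]):
        if idx in y_by_index:
            keep_rows.append(row)
            y_used.append(y_by_index[idx])
    X = dm.X[keep_rows]
    y_used = np.asarray(y_used, dtype=float)
    if len(y_used) < 2:
        raise FatalError("series too small after member failures", stage="idata")

    conformal_block = None
    folds_used = 0
    estimator = conformal_state = scaler = None
    if combination == "meta":
        meta_hp = params.get("ensemble.meta")
        spec = EstimatorSpec(
            meta_hp.get("method", "RF"),
            task,
            meta_hp.get("hyperparameters", {}),
            meta_hp.get("seed", params.get("learner.seed")),
        )
        conf = params.get("conformal")
        settings = ConformalSettings(
            conf["enabled"], conf["confidence"], conf["calibration_fraction"], conf["seed"]
        )
        scaler = fit_scaler(X, params.get("descriptors.scaling"))
        Xs = apply_scaler(X, scaler)
        estimator, conformal_state = fit_conformal(Xs, y_used, spec, settings)
        cv = cross_validate(
            Xs, y_used, spec, settings,
            folds=params.get("validation.folds"), seed=params.get("validation.seed"),
        )
        folds_used = cv.folds
        fitted = np.asarray(estimator.predict(Xs), dtype=float).ravel()
        oof = cv.y_pred
        if cv.conformal is not None:
            conformal_block = conformal_stats(cv.conformal, y_used)
    else:
        combined = _combined_vector(X, combination, endpoint)
        conclusive = [i for i, v in enumerate(combined) if v != INCONCLUSIVE]
        fitted = np.asarray([float(combined[i]) for i in conclusive])
        oof = fitted
        y_eval = y_used[conclusive]

    if combination == "meta":
        y_eval = y_used
    if task == "classification":
        fitting = classification_stats(confusion_from_predictions(y_eval, fitted))
        prediction = classification_stats(confusion_from_predictions(y_eval, oof))
    else:
        fitting = regression_stats(RegressionPairs(y_eval, fitted), "fitting")
        prediction = regression_stats(RegressionPairs(y_eval, oof), "prediction")

    report = QualityReport(
        endpoint_type=endpoint,
        fitting=fitting,
        prediction=prediction,
        conformal=conformal_block,
        series=series_stats(AnnotatedSeries([], y_used, params.get("annotation.field"), endpoint)),
        chemspace={},
        folds=folds_used,
        n_used=len(y_used),
        failures=[list(f) for f in dm.failures],
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )

    params.save(dev / ParameterSet.FILENAME)
    bundle = {
        "estimator": estimator,
        "conformal_state": conformal_state,
        "members": members,
        "member_ids": {name: repo.unique_id(name) for name, _v in members},
        "combination": combination,
    }
    joblib.dump(bundle, dev / "estimator.bin")
    manifest = {
        "method": f"ensemble:{combination}",
        "members": [[n, v] for n, v in members],
        "library_versions": library_versions(),
    }
    (dev / "estimator.manifest").write_text(yaml.safe_dump(manifest, sort_keys=True))
    if scaler is not None:
        from .workflows import _save_scaler

        _save_scaler(dev / "scaler.json", scaler)
    report.save(dev / QualityReport.FILENAME)
    repo.autofill_documentation(model_name, params, report)
    return report


def predict_ensemble(
    repo: ModelRepository, model_name: str, version, input_path, confidence=None
):
    """Predict with an ensemble: per-member detail plus the combined result."""
    from .workflows import PredictionRecord, _load_scaler

    vdir = repo.version_dir(model_name, version)
    params = ParameterSet.load(vdir)
    endpoint = params.get("annotation.endpoint_type")
    task = "classification" if endpoint == "qualitative" else "regression"
    combination = params.get("ensemble.combination")
    confidence = confidence if confidence is not None else params.get("conformal.confidence")

    bundle = joblib.load(vdir / "estimator.bin")
    members = bundle["members"]
    for name, ver in members:
        try:
            repo.version_dir(name, ver)
        except Exception as exc:
            raise FatalError(
                f"ensemble member {name!r} v{ver} was deleted since build; "
                f"traceability is broken: {exc}",
                stage="apply",
            )
    dm, member_records = ensemble_matrix(repo, members, input_path, confidence)

    combined_values = {}
    if combination == "meta":
        scaler = _load_scaler(vdir / "scaler.json")
        Xs = apply_scaler(dm.X, scaler)
        estimator, state = bundle["estimator"], bundle["conformal_state"]
        if state is not None:
            out = conformal_predict(estimator, state, Xs, confidence)
        else:
            out = None
            points = np.asarray(estimator.predict(Xs)).ravel()
    else:
        out = None

    n_inputs = len(member_records[0][2].compounds)
    compounds = []
    row = 0
    for i in range(n_inputs):
        name = member_records[0][2].compounds[i]["name"]
        entry = {"name": name, "source_index": i}
        member_detail = []
        for mname, mver, record in member_records:
            c = record.compounds[i]
            detail = {
                "model": mname,
                "version": mver,
                "unique_id": record.header["unique_id"],
                "status": c["status"],
            }
            for key in ("value", "y_min", "y_max", "outcome", "set", "p_values", "reason"):
                if key in c:
                    detail[key] = c[key]
            member_detail.append(detail)
        entry["members"] = member_detail
        if not dm.success_mask[i]:
            entry["status"] = "failed"
            entry["reason"] = next(
                (f[2] for f in dm.failures if f[0] == i), "failed by a member"
            )
            compounds.append(entry)
            continue
        entry["status"] = "ok"
        if combination == "meta":
            if out is not None and task == "regression":
                entry["value"] = float(out.point[row])
                entry["y_min"] = float(out.y_min[row])
                entry["y_max"] = float(out.y_max[row])
            elif out is not None:
                entry["value"] = int(out.point[row])
                entry["outcome"] = out.outcomes[row]
            else:
                entry["value"] = (
                    int(points[row]) if task == "classification" else float(points[row])
                )
        else:
            result = combine(dm.X[row], combination, endpoint)
            if result == INCONCLUSIVE:
                entry["outcome"] = INCONCLUSIVE
            else:
                entry["value"] = result
        compounds.append(entry)
        row += 1

    header = {
        "model_name": model_name,
        "unique_id": repo.unique_id(model_name),
        "version": int(version),
        "confidence": float(confidence),
        "endpoint_type": endpoint,
        "framework_version": framework_version,
        "combination": combination,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return PredictionRecord(header=header, compounds=compounds)
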