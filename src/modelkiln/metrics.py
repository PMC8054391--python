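"""Model quality statistics and the persistent quality report.

Implements the standard QSAR quality panel: sensitivity, specificity and
MCC for qualitative endpoints; SDEC/SDEP (standard deviation of the errors
in calculation/prediction) and r-squared/q-squared for quantitative ones;
plus conformal coverage, conformal accuracy and mean interval width.

Conventions (recorded in the report manifest):

* MCC with any zero factor in the denominator is reported as 0.
* r2/q2 use the determination coefficient ``1 - SS_res / SS_tot``.
* conformal accuracy divides correct *conclusive* predictions by the total
  sample count, so inconclusive predictions count against it.
* classification coverage counts the both-classes set as covering (the
  true class is inside the region).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .chemio import AnnotatedSeries
from .learners import (
    ConformalOutput,
    OUTCOME_NEGATIVE,
    OUTCOME_POSITIVE,
)

__all__ = [
    "ConfusionCounts",
    "RegressionPairs",
    "QualityReport",
    "confusion_from_predictions",
    "classification_stats",
    "regression_stats",
    "conformal_stats",
    "series_stats",
]

UNDEFINED = "undefined"  # marker for stats with no defined value

CONVENTIONS = {
    "r2_q2_formula": "determination coefficient 1 - SS_res/SS_tot",
    "mcc_zero_denominator": "reported as 0",
    "conformal_accuracy_denominator": "total samples (inconclusives count against)",
    "classification_coverage": "true class inside the prediction set (both-classes set covers)",
}


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class RegressionPairs:
    y_exp: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self):
        self.y_exp = np.asarray(self.y_exp, dtype=float)
        self.y_pred = np.asarray(self.y_pred, dtype=float)
        if len(self.y_exp) != len(self.y_pred):
            raise ValueError("y_exp and y_pred lengths differ")
        if len(self.y_exp) < 2:
            raise ValueError("need at least 2 pairs")

    @property
    def y_mean(self) -> float:
        return float(self.y_exp.mean())


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Tally a binary confusion table; class 1 is positive."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def classification_stats(c: ConfusionCounts) -> dict:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), and MCC.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero
    factor in the denominator makes MCC undefined and it is reported as 0.
    """
    for v in (c.TP, c.TN, c.FP, c.FN):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    if c.n < 1:
        raise ValueError("empty confusion table")
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else 0.0
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else 0.0
    denom = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    mcc = 0.0 if denom == 0 else ((c.TP * c.TN) - (c.FP * c.FN)) / math.sqrt(denom)
    return {"sensitivity": float(sens), "specificity": float(spec), "mcc": float(mcc)}


def regression_stats(p: RegressionPairs, mode: str = "fitting") -> dict:
    """SDEC (fitting) or SDEP (prediction) plus r2 or q2.

    SDEC = SDEP = sqrt(sum((y_exp - y_pred)^2) / n), applied to fitted
    values or out-of-fold predictions respectively; the determination
    coefficient is 1 - SS_res/SS_tot and is undefined for constant y_exp.
    """
    if mode not in ("fitting", "prediction"):
        raise ValueError(f"mode must be fitting or prediction, got {mode!r}")
    residuals = p.y_exp - p.y_pred
    ss_res = float(np.sum(residuals**2))
    n = len(p.y_exp)
    sd_error = math.sqrt(ss_res / n)
    ss_tot = float(np.sum((p.y_exp - p.y_mean) ** 2))
    det = UNDEFINED if ss_tot == 0 else float(1.0 - ss_res / ss_tot)
    if mode == "fitting":
        return {"sdec": sd_error, "r2": det}
    return {"sdep": sd_error, "q2": det}


def conformal_stats(output: ConformalOutput, y_true) -> dict:
    """Conformal coverage, accuracy, and (quantitative) mean interval width.

    coverage — fraction of samples whose true value lies inside the
    predicted region (interval, or class set containing the true class);
    accuracy — fraction whose prediction is a conclusive, correct single
    outcome; mean_interval — mean |Y_max - Y_min| (regression only).
    """
    y_true = np.asarray(y_true, dtype=float)
    n = len(y_true)
    if output.task == "regression":
        if len(output.point) != n:
            raise ValueError("length mismatch between outputs and truth")
        inside = (y_true >= output.y_min) & (y_true <= output.y_max)
        widths = np.abs(output.y_max - output.y_min)
        return {
            "coverage": float(inside.mean()),
            "accuracy": float(inside.mean()),
            "mean_interval": float(widths.mean()),
        }
    if len(output.sets) != n:
        raise ValueError("length mismatch between outputs and truth")
    covered = sum(
        1 for i in range(n) if int(y_true[i]) in output.sets[i]
    )
    correct = 0
    for i in range(n):
        if output.outcomes[i] == OUTCOME_POSITIVE and int(y_true[i]) == 1:
            correct += 1
        elif output.outcomes[i] == OUTCOME_NEGATIVE and int(y_true[i]) == 0:
            correct += 1
    return {"coverage": covered / n, "accuracy": correct / n, "mean_interval": None}


def series_stats(series: AnnotatedSeries) -> dict:
    """Training-series composition: class ratio or value-distribution quantiles."""
    y = np.asarray(series.y, dtype=float)
    if len(y) == 0:
        raise ValueError("empty series")
    if series.endpoint_type == "qualitative":
        pos = int(np.sum(y == 1))
        neg = int(np.sum(y == 0))
        out = {
            "positives": pos,
            "negatives": neg,
            "ratio": float(pos / (pos + neg)),
        }
        if pos == 0 or neg == 0:
            out["warning"] = "single-class series: severe class imbalance"
        return out
    q = np.quantile(y, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {
        "min": float(q[0]),
        "q1": float(q[1]),
        "median": float(q[2]),
        "q3": float(q[3]),
        "max": float(q[4]),
    }


# ---------------------------------------------------------------------------
# Quality report


def _to_plain(obj):
    """Recursively convert numpy scalars/arrays so yaml round-trips exactly."""
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _rounded(obj, digits=3):
    if isinstance(obj, dict):
        return {k: _rounded(v, digits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_rounded(v, digits) for v in obj]
    if isinstance(obj, float):
        return round(obj, digits)
    return obj


@dataclass
class QualityReport:
    """Everything the build run measured, persisted in the model folder.

    Saved as ``model-results.yaml``; saving, loading and saving again is
    byte-identical, so reports survive across sessions unchanged.
    """

    endpoint_type: str = "quantitative"
    fitting: dict = field(default_factory=dict)
    prediction: dict = field(default_factory=dict)
    conformal: dict | None = None
    series: dict = field(default_factory=dict)
    chemspace: dict = field(default_factory=dict)
    folds: int = 5
    n_used: int = 0
    failures: list = field(default_factory=list)
    duplicates: list = field(default_factory=list)
    timestamp: str = ""
    conventions: dict = field(default_factory=lambda: dict(CONVENTIONS))

    FILENAME = "model-results.yaml"

    def to_dict(self) -> dict:
        full = _to_plain(
            {
                "endpoint_type": self.endpoint_type,
                "fitting": self.fitting,
                "prediction": self.prediction,
                "conformal": self.conformal,
                "series": self.series,
                "chemspace": self.chemspace,
                "folds": self.folds,
                "n_used": self.n_used,
                "failures": self.failures,
                "duplicates": self.duplicates,
                "timestamp": self.timestamp,
                "conventions": self.conventions,
            }
        )
        full["display"] = _rounded(
            {
                "fitting": full["fitting"],
                "prediction": full["prediction"],
                "conformal": full["conformal"],
            }
        )
        return full

    @classmethod
    def from_dict(cls, data: dict) -> "QualityReport":
        data = dict(data)
        data.pop("display", None)
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True, default_flow_style=False)

    @classmethod
    def load(cls, path) -> "QualityReport":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
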