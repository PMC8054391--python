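"""The per-model parameter file: the model blueprint.

Every model folder carries a ``parameters.yml`` describing completely how
the model is (re)built: normalization, annotation field, descriptor set,
scaling, learner, conformal settings, validation, labels.  A flat,
two-level key structure with dotted overrides (``learner.method=RF``)
covers both the library API and the CLI ``--param`` flag.

Unknown keys are rejected outright — a typo in a blueprint must fail at
load, not silently fall back to a default.
"""

from __future__ import annotations

import copy
import hashlib
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["ParameterSet", "DEFAULTS"]

DEFAULTS: dict = {
    "normalization": {
        "method": "largest_fragment",  # none | largest_fragment | adapter name
    },
    "annotation": {
        "field": None,  # the only parameter with no default
        "endpoint_type": "quantitative",  # quantitative | qualitative
        "positive_synonyms": ["1", "positive", "pos", "active", "true"],
        "negative_synonyms": ["0", "negative", "neg", "inactive", "false"],
    },
    "descriptors": {
        "method": "composition",
        "scaling": "autoscale",  # raw | autoscale
    },
    "compute": {
        "n_chunks": 1,
    },
    "learner": {
        "method": "RF",  # RF | SVM | PLS | GBM
        "hyperparameters": {},  # free map, passed to the estimator
        "seed": 46,
    },
    "tune": {
        "grid": {},  # hyperparameter grid for internal CV tuning; off when empty
    },
    "conformal": {
        "enabled": True,
        "confidence": 0.8,
        "calibration_fraction": 0.3,
        "seed": 46,
    },
    "validation": {
        "folds": 5,
        "seed": 46,
    },
    "chemspace": {
        "components": 2,
    },
    "ensemble": {
        "members": [],  # list of [name, version]; non-empty makes this an ensemble model
        "combination": "mean",  # majority | mean | median | meta
        "meta": {},  # EstimatorSpec-style map when combination == meta
    },
    "labels": {
        "Maturity": "",
        "Type": "",
        "Subtype": "",
        "Endpoint": "",
        "Species": "",
    },
}

# Sections whose values are free-form maps/lists, exempt from key validation.
_FREE_SECTIONS = {
    ("learner", "hyperparameters"),
    ("tune", "grid"),
    ("ensemble", "meta"),
}


class ParameterSet:
    """Validated two-level parameter tree with dotted access."""

    def __init__(self, data: dict | None = None):
        self._data = copy.deepcopy(DEFAULTS)
        if data:
            self.update(data)

    # -- access ------------------------------------------------------------

    def get(self, dotted: str):
        section, _, key = dotted.partition(".")
        if not key:
            return copy.deepcopy(self._data[section])
        return copy.deepcopy(self._data[section][key])

    def set(self, dotted: str, value) -> None:
        section, _, key = dotted.partition(".")
        if section not in self._data:
            raise ConfigurationError(f"unknown parameter section {section!r}")
        if not key:
            raise ConfigurationError("use section.key form")
        if key not in DEFAULTS[section] and (section, key) not in _FREE_SECTIONS:
            raise ConfigurationError(f"unknown parameter {dotted!r}")
        self._data[section][key] = value

    def update(self, data: dict) -> None:
        for section, block in data.items():
            if section not in self._data:
                raise ConfigurationError(f"unknown parameter section {section!r}")
            if not isinstance(block, dict):
                raise ConfigurationError(f"section {section!r} must be a mapping")
            for key, value in block.items():
                if key not in DEFAULTS[section] and (section, key) not in _FREE_SECTIONS:
                    raise ConfigurationError(f"unknown parameter {section}.{key!r}")
                self._data[section][key] = copy.deepcopy(value)

    def apply_overrides(self, overrides) -> None:
        """Apply dotted overrides from a dict or ``key=value`` strings.

        String values are coerced through YAML so ``--param
        validation.folds=7`` arrives as an int.
        """
        if overrides is None:
            return
        if isinstance(overrides, dict):
            items = overrides.items()
        else:
            items = []
            for entry in overrides:
                key, sep, value = entry.partition("=")
                if not sep:
                    raise ConfigurationError(f"override {entry!r} is not key=value")
                items.append((key, value))
        for key, value in items:
            if isinstance(value, str):
                value = yaml.safe_load(value)
            self.set(key, value)

    def to_dict(self) -> dict:
        return copy.deepcopy(self._data)

    # -- persistence --------------------------------------------------------

    FILENAME = "parameters.yml"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._data, fh, sort_keys=True, default_flow_style=False)

    @classmethod
    def load(cls, path) -> "ParameterSet":
        path = Path(path)
        if path.is_dir():
            path = path / cls.FILENAME
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data)

    def digest(self) -> str:
        """Stable digest of the blueprint, recorded in run logs."""
        canon = yaml.safe_dump(self._data, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    # -- semantic checks ----------------------------------------------------

    def validate_for_build(self) -> None:
        if not self.get("ensemble.members") and not self.get("annotation.field"):
            raise ConfigurationError(
                "annotation.field must be set: it is the only parameter without a default"
            )
        endpoint = self.get("annotation.endpoint_type")
        if endpoint not in ("quantitative", "qualitative"):
            raise ConfigurationError(f"unknown endpoint_type {endpoint!r}")
        conf = self.get("conformal.confidence")
        if not 0.0 < conf < 1.0:
            raise ConfigurationError(f"conformal.confidence must be in (0,1), got {conf}")
        if self.get("validation.folds") < 2:
            raise ConfigurationError("validation.folds must be >= 2")
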