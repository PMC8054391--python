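"""Molecular descriptor computation, scaling, and caching.

The built-in ``composition`` descriptor set works directly on the record
graph (counts, cyclomatic ring number, molecular weight from a fixed atomic
mass table) so the whole framework is testable without any chemistry
toolkit.  Toolkit descriptor sets (RDKit properties, fingerprints, ...)
plug in through the adapter registry behind the same records -> matrix
interface.

Chunked computation is a throughput contract only: the resulting matrix is
bit-identical for any number of chunks.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from joblib import Parallel, delayed

from .chemio import MoleculeRecord, _components
from .errors import ConfigurationError, FatalError

__all__ = [
    "DescriptorMatrix",
    "ScalerState",
    "compute_descriptors",
    "fit_scaler",
    "apply_scaler",
    "DescriptorCache",
    "series_fingerprint",
    "register_descriptor_set",
    "DESCRIPTOR_ADAPTERS",
    "COMPOSITION_NAMES",
    "ATOMIC_MASSES",
]

# Fixed atomic mass table (standard atomic weights, 2021 IUPAC abridged).
ATOMIC_MASSES = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Si": 28.085, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "Se": 78.971, "Br": 79.904, "I": 126.904,
}

_COUNTED_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")

COMPOSITION_NAMES = [
    "heavy_atoms",
    "bond_count",
    "ring_count",
    "mol_weight",
] + [f"count_{el}" for el in _COUNTED_ELEMENTS]


@dataclass
class DescriptorMatrix:
    """The X block: one row per successfully processed input record."""

    X: np.ndarray
    names: list
    row_ids: list
    success_mask: np.ndarray
    failures: list = field(default_factory=list)  # (source_index, name, reason)

    def validate(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise ValueError("X must be n x M with M >= 1")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if self.X.shape[0] != int(self.success_mask.sum()):
            raise ValueError("rows must align with success_mask")


@dataclass
class ScalerState:
    """Training-time column centers/scales, reused verbatim at prediction."""

    method: str  # "raw" | "autoscale"
    centers: np.ndarray
    scales: np.ndarray


DESCRIPTOR_ADAPTERS: dict = {}


def register_descriptor_set(name: str, func: Callable, metric: str = "euclidean") -> None:
    """Register a toolkit descriptor set.

    ``func(record) -> (values: 1d array, names: list)``; raising inside the
    adapter fails that molecule only.  ``metric`` declares the similarity
    metric appropriate for the set (e.g. ``tanimoto`` for binary
    fingerprints), consumed by the chemical-space module.
    """
    DESCRIPTOR_ADAPTERS[name] = (func, metric)


def _composition_row(rec: MoleculeRecord) -> np.ndarray:
    elements = [el for el, _ in rec.atoms]
    unknown = [el for el in elements if el not in ATOMIC_MASSES]
    if unknown:
        raise ValueError(f"unknown element(s) {sorted(set(unknown))} in mass table")
    n_atoms = len(rec.atoms)
    n_bonds = len(rec.bonds)
    n_comp = len(_components(n_atoms, rec.bonds)) if n_atoms else 0
    rings = n_bonds - n_atoms + n_comp  # cyclomatic number
    mw = float(sum(ATOMIC_MASSES[el] for el in elements))
    counts = [float(sum(1 for el in elements if el == e)) for e in _COUNTED_ELEMENTS]
    return np.array([float(n_atoms), float(n_bonds), float(rings), mw] + counts)


def _descriptor_func(method: str):
    if method == "composition":
        return _composition_row, COMPOSITION_NAMES
    if method in DESCRIPTOR_ADAPTERS:
        func, _metric = DESCRIPTOR_ADAPTERS[method]
        return func, None  # adapter reports its own names per call
    raise ConfigurationError(
        f"unknown descriptor method {method!r}; "
        f"built-ins: composition; adapters: {sorted(DESCRIPTOR_ADAPTERS)}"
    )


def _compute_chunk(records, method):
    func, _ = _descriptor_func(method)
    rows = []
    for rec in records:
        if rec.status != "ok":
            rows.append((None, rec.failure_reason))
            continue
        try:
            out = func(rec)
            values = np.asarray(out[0] if isinstance(out, tuple) else out, dtype=float)
            if not np.all(np.isfinite(values)):
                raise ValueError("non-finite descriptor value")
            rows.append((values, ""))
        except Exception as exc:  # noqa: BLE001 - per-molecule isolation
            rows.append((None, f"descriptor computation failed: {exc}"))
    return rows


def compute_descriptors(
    records, method: str = "composition", n_chunks: int = 1
) -> DescriptorMatrix:
    """Compute the descriptor matrix for a record series.

    The series is split into ``n_chunks`` contiguous sub-series computed
    independently (parallelizable) and reassembled in input order, so the
    result is identical for any chunk count.  Records that fail descriptor
    computation (unknown elements, adapter errors, non-finite values) get
    ``success_mask=False`` with a reason rather than being imputed.
    """
    if n_chunks < 1:
        raise ConfigurationError("n_chunks must be >= 1")
    _descriptor_func(method)  # validate method before any work
    if method == "composition":
        names = list(COMPOSITION_NAMES)
    else:
        names = None

    records = list(records)
    n_chunks = min(n_chunks, max(len(records), 1))
    chunks = np.array_split(np.arange(len(records)), n_chunks)
    if n_chunks == 1:
        chunk_rows = [_compute_chunk(records, method)]
    else:
        chunk_rows = Parallel(n_jobs=min(n_chunks, 4), prefer="threads")(
            delayed(_compute_chunk)([records[i] for i in idx], method) for idx in chunks
        )

    rows, row_ids, mask, failures = [], [], [], []
    flat = [item for chunk in chunk_rows for item in chunk]
    for rec, (values, reason) in zip(records, flat):
        if values is None:
            mask.append(False)
            failures.append((rec.source_index, rec.name, reason))
        else:
            mask.append(True)
            rows.append(values)
            row_ids.append(rec.name)
    if not rows:
        raise FatalError("empty X matrix: every record failed", stage="idata")

    X = np.vstack(rows)
    if names is None:
        # adapters may return (values, names); re-query once for the labels
        func, _ = _descriptor_func(method)
        out = func(next(r for r in records if r.status == "ok"))
        names = (
            list(out[1])
            if isinstance(out, tuple)
            else [f"{method}_{j}" for j in range(X.shape[1])]
        )
    dm = DescriptorMatrix(
        X=X,
        names=names,
        row_ids=row_ids,
        success_mask=np.asarray(mask, dtype=bool),
        failures=failures,
    )
    dm.validate()
    return dm


# ---------------------------------------------------------------------------
# Scaling


def fit_scaler(X: np.ndarray, method: str = "autoscale") -> ScalerState:
    """Fit column centers/scales on the training matrix.

    ``autoscale`` standardizes to mean 0 / unit sample variance; columns
    with zero variance get scale 1 (they become centered zeros).  ``raw``
    is the identity transform.
    """
    X = np.asarray(X, dtype=float)
    if method == "raw":
        return ScalerState("raw", np.zeros(X.shape[1]), np.ones(X.shape[1]))
    if method == "autoscale":
        centers = X.mean(axis=0)
        scales = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        scales = np.where(scales > 0, scales, 1.0)
        return ScalerState("autoscale", centers, scales)
    raise ConfigurationError(f"unknown scaling method {method!r}; use raw or autoscale")


def apply_scaler(X: np.ndarray, state: ScalerState) -> np.ndarray:
    """Apply stored training-time scaling; never refits."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(state.centers):
        raise FatalError(
            f"descriptor mismatch: X has {X.shape[1]} columns, "
            f"scaler expects {len(state.centers)}",
            stage="idata",
        )
    return (X - state.centers) / state.scales


# ---------------------------------------------------------------------------
# Caching


def series_fingerprint(input_bytes: bytes, normalization: str, method: str, extra: str = "") -> str:
    """Content digest keying the descriptor cache.

    Keyed by input *bytes* (not path or mtime) plus every setting that
    influences the matrix, so copied files hit and any settings change
    invalidates.
    """
    h = hashlib.sha256()
    h.update(input_bytes)
    h.update(f"|norm={normalization}|desc={method}|{extra}".encode())
    return h.hexdigest()


class DescriptorCache:
    """Descriptor matrix cache stored inside the model folder.

    One matrix file (`descriptors.npz`) with a sidecar digest; a corrupt
    entry is treated as a miss with a warning, never an error.
    """

    def __init__(self, directory):
        self.dir = Path(directory)

    @property
    def _matrix_path(self) -> Path:
        return self.dir / "descriptors.npz"

    @property
    def _digest_path(self) -> Path:
        return self.dir / "descriptors.digest"

    def get(self, fingerprint: str):
        if not (self._matrix_path.exists() and self._digest_path.exists()):
            return None
        try:
            meta = json.loads(self._digest_path.read_text())
            if meta.get("fingerprint") != fingerprint:
                return None
            with np.load(self._matrix_path, allow_pickle=False) as data:
                dm = DescriptorMatrix(
                    X=data["X"],
                    names=[str(s) for s in data["names"]],
                    row_ids=[str(s) for s in data["row_ids"]],
                    success_mask=data["success_mask"],
                    failures=[tuple(f) for f in meta.get("failures", [])],
                )
            dm.validate()
            return dm
        except Exception as exc:  # noqa: BLE001 - corrupt cache is a soft miss
            warnings.warn(f"corrupt descriptor cache entry ignored: {exc}")
            return None

    def put(self, fingerprint: str, dm: DescriptorMatrix) -> None:
        self.dir.mkdir(parents=True, exist_ok=True)
        np.savez(
            self._matrix_path,
            X=dm.X,
            names=np.asarray(dm.names),
            row_ids=np.asarray(dm.row_ids),
            success_mask=dm.success_mask,
        )
        self._digest_path.write_text(
            json.dumps(
                {
                    "fingerprint": fingerprint,
                    "failures": [list(f) for f in dm.failures],
                }
            )
        )
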