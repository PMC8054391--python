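"""Chemical-space diagnostics: PCA scores, DModX, nearest neighbours.

A two-component PCA of the scaled training matrix gives the scores
scatterplot data; query compounds are centered with the *training* means
and projected on the stored loadings (never refit).  DModX — the distance
of an observation to the PCA model, SIMCA convention — is the
root-mean-square reconstruction residual normalized by the pooled training
residual scale s0, so an average training compound sits near 1 and values
well above 1 flag structures with features absent from the training series
(outside the applicability domain).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import FatalError

__all__ = ["SpaceModel", "fit_space", "project", "dmodx", "nearest_training"]


@dataclass
class SpaceModel:
    loadings: np.ndarray  # M x k, orthonormal columns
    scores: np.ndarray  # n x k training scores
    means: np.ndarray  # training column means used for centering
    s0: float  # pooled residual standard deviation
    k: int

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "loadings": self.loadings.tolist(),
                    "scores": self.scores.tolist(),
                    "means": self.means.tolist(),
                    "s0": self.s0,
                    "k": self.k,
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "SpaceModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            loadings=np.asarray(d["loadings"], dtype=float),
            scores=np.asarray(d["scores"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            s0=float(d["s0"]),
            k=int(d["k"]),
        )


def _sign_fix(loadings: np.ndarray) -> np.ndarray:
    """Deterministic component signs: largest-magnitude loading positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_space(X_scaled: np.ndarray, k: int = 2) -> SpaceModel:
    """PCA of the scaled training matrix, keeping k components.

    s0 pools the residual variance of the training reconstructions over
    (M - k) residual dimensions and (n - k - 1) degrees of freedom, so
    DModX of an average training compound is close to 1 by construction.
    """
    X = np.asarray(X_scaled, dtype=float)
    n, m = X.shape
    if m < k:
        raise FatalError(f"cannot fit {k} components on {m} descriptors", stage="learn")
    if n <= k:
        raise FatalError(f"need more than {k} training rows, got {n}", stage="learn")
    means = X.mean(axis=0)
    centered = X - means
    _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = _sign_fix(vt[:k].T)
    scores = centered @ loadings
    residual = centered - scores @ loadings.T
    dof = (m - k) * max(n - k - 1, 1)
    s0 = math.sqrt(float(np.sum(residual**2)) / dof) if m > k else 0.0
    return SpaceModel(loadings=loadings, scores=scores, means=means, s0=s0, k=k)


def project(space: SpaceModel, X_query: np.ndarray) -> np.ndarray:
    """Project queries on the stored loadings, centered with training means."""
    X = np.atleast_2d(np.asarray(X_query, dtype=float))
    if X.shape[1] != len(space.means):
        raise FatalError(
            f"descriptor mismatch: query has {X.shape[1]} columns, "
            f"space expects {len(space.means)}",
            stage="apply",
        )
    return (X - space.means) @ space.loadings


def dmodx(space: SpaceModel, X_query: np.ndarray) -> np.ndarray:
    """Normalized distance to the PCA model per query row.

    DModX_i = sqrt(sum_j e_ij^2 / (M - k)) / s0 with e the reconstruction
    residual.  Zero residual gives exactly 0; a degenerate space with zero
    pooled residual maps any nonzero residual to infinity.
    """
    X = np.atleast_2d(np.asarray(X_query, dtype=float))
    m = X.shape[1]
    if m <= space.k:
        raise FatalError(f"DModX undefined: M={m} <= k={space.k}", stage="apply")
    centered = X - space.means
    scores = centered @ space.loadings
    residual = centered - scores @ space.loadings.T
    rms = np.sqrt(np.sum(residual**2, axis=1) / (m - space.k))
    if space.s0 > 1e-12:
        return rms / space.s0
    return np.where(rms <= 1e-8, 0.0, np.inf)


def nearest_training(
    X_train: np.ndarray,
    train_names,
    train_annotations,
    X_query: np.ndarray,
    n_neighbors: int = 5,
) -> list:
    """Closest training compounds per query, on the model's descriptor space.

    Euclidean distance on the scaled descriptors; ties broken by training
    order (stable sort); n_neighbors is capped at the training size.
    Returns, per query row, a list of (name, annotation, distance).
    """
    X_train = np.asarray(X_train, dtype=float)
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    if X_query.shape[1] != X_train.shape[1]:
        raise FatalError(
            f"descriptor mismatch: query has {X_query.shape[1]} columns, "
            f"training has {X_train.shape[1]}",
            stage="apply",
        )
    n = X_train.shape[0]
    n_neighbors = min(n_neighbors, n)
    results = []
    for q in X_query:
        dists = np.sqrt(np.sum((X_train - q) ** 2, axis=1))
        order = np.argsort(dists, kind="stable")[:n_neighbors]
        results.append(
            [
                (str(train_names[i]), float(np.asarray(train_annotations)[i]), float(dists[i]))
                for i in order
            ]
        )
    return results
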