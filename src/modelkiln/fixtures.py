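"""Deterministic synthetic training series with known structure-activity truth.

Generates structurally valid V2000 molecules as random linear/branched/ring
C-N-O graphs within valence rules (C<=4, N<=3, O<=2, single bonds), and an
activity that is by construction a linear function of the built-in
composition descriptors plus Gaussian noise:

    latent_i = sum_d w_d * descriptor_d(mol_i) + Normal(0, noise_sd)

Quantitative endpoints use the latent directly; qualitative endpoints
threshold it (default threshold: the latent median, giving a balanced
series).  The truth table (weights, latents, noise draws) is written next
to the SDFile so recovery tests can compare against ground truth.

The same spec always produces byte-identical files.  No attempt is made at
drug-like chemistry — these series exercise the machinery, not the biology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .chemio import MoleculeRecord, write_sdf
from .descriptors import COMPOSITION_NAMES, _composition_row
from .errors import ConfigurationError

__all__ = ["FixtureSpec", "generate_series", "generate_malformed", "DEFAULT_WEIGHTS"]

_VALENCE = {"C": 4, "N": 3, "O": 2}
_ELEMENTS = ("C", "N", "O")
_ELEMENT_P = (0.7, 0.15, 0.15)

DEFAULT_WEIGHTS = {
    "heavy_atoms": 0.25,
    "ring_count": 1.0,
    "count_N": 0.6,
    "count_O": -0.8,
}


@dataclass
class FixtureSpec:
    n: int = 60
    seed: int = 46
    endpoint_type: str = "quantitative"
    noise_sd: float = 0.0
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    threshold: float | None = None  # qualitative; None -> latent median
    annotation_field: str = "activity"

    def __post_init__(self):
        if self.n < 4:
            raise ConfigurationError("fixture series needs n >= 4")
        unknown = set(self.weights) - set(COMPOSITION_NAMES)
        if unknown:
            raise ConfigurationError(
                f"weights reference unknown descriptors: {sorted(unknown)}"
            )


def _random_molecule(rng: np.random.Generator, index: int) -> MoleculeRecord:
    n_atoms = int(rng.integers(5, 15))
    elements = [str(rng.choice(_ELEMENTS, p=_ELEMENT_P)) for _ in range(n_atoms)]
    degree = [0] * n_atoms
    bonds = []
    # random spanning tree respecting valences
    for i in range(1, n_atoms):
        open_parents = [j for j in range(i) if degree[j] < _VALENCE[elements[j]]]
        if not open_parents:
            elements[i] = "C"  # should not happen; keep the graph connected
            open_parents = [i - 1]
        parent = int(rng.choice(open_parents))
        bonds.append((parent, i, 1))
        degree[parent] += 1
        degree[i] += 1
    # optionally close one ring between non-adjacent open atoms
    if n_atoms >= 5 and rng.random() < 0.5:
        adjacent = {(a, b) for a, b, _ in bonds} | {(b, a) for a, b, _ in bonds}
        candidates = [
            (a, b)
            for a in range(n_atoms)
            for b in range(a + 2, n_atoms)
            if degree[a] < _VALENCE[elements[a]]
            and degree[b] < _VALENCE[elements[b]]
            and (a, b) not in adjacent
        ]
        if candidates:
            a, b = candidates[int(rng.integers(len(candidates)))]
            bonds.append((a, b, 1))
    return MoleculeRecord(
        name=f"mol_{index:04d}",
        atoms=[(el, 0) for el in elements],
        bonds=bonds,
        source_index=index,
    )


def _build_records(spec: FixtureSpec):
    rng = np.random.default_rng(spec.seed)
    records = [_random_molecule(rng, i) for i in range(spec.n)]
    desc = np.vstack([_composition_row(r) for r in records])
    w = np.array([spec.weights.get(name, 0.0) for name in COMPOSITION_NAMES])
    signal = desc @ w
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n) if spec.noise_sd > 0 else np.zeros(spec.n)
    latent = signal + noise

    if spec.endpoint_type == "qualitative":
        threshold = float(np.median(latent)) if spec.threshold is None else spec.threshold
        y = (latent > threshold).astype(int)
        values = [str(int(v)) for v in y]
    else:
        threshold = None
        y = latent
        values = [f"{v:.6f}" for v in latent]

    for rec, v in zip(records, values):
        rec.properties[spec.annotation_field] = v
    return records, latent, noise, y, threshold


def _write_truth(path, spec: FixtureSpec, latent, noise, y, threshold) -> None:
    lines = ["# weights: " + json.dumps(spec.weights, sort_keys=True)]
    if threshold is not None:
        lines.append(f"# threshold: {threshold!r}")
    lines.append("name\tlatent\tnoise\ty")
    for i in range(len(latent)):
        yi = int(y[i]) if spec.endpoint_type == "qualitative" else f"{y[i]:.6f}"
        lines.append(f"mol_{i:04d}\t{latent[i]:.6f}\t{noise[i]:.6f}\t{yi}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def generate_series(spec: FixtureSpec, sdf_path, truth_path=None):
    """Write the synthetic SDFile (and optional truth table); returns records."""
    records, latent, noise, y, threshold = _build_records(spec)
    write_sdf(records, sdf_path)
    if truth_path is not None:
        _write_truth(truth_path, spec, latent, noise, y, threshold)
    return records


_CORRUPTION_MODES = ("bad_counts", "truncated", "missing_annotation")


def generate_malformed(spec: FixtureSpec, k: int, sdf_path, truth_path=None):
    """Generate a series with k corrupted entries at known positions.

    Corruption cycles through three modes: a mangled counts line, a
    truncated connection table, and a stripped annotation field (the last
    parses fine but fails at annotation extraction).  Returns the planted
    ``[(entry_index, mode), ...]`` so tests can match the run report.
    """
    if k >= spec.n:
        raise ConfigurationError("k must be smaller than n")
    generate_series(spec, sdf_path, truth_path)
    if k == 0:
        return []
    rng = np.random.default_rng(spec.seed + 1)
    indices = sorted(int(i) for i in rng.choice(spec.n, size=k, replace=False))
    planted = [(idx, _CORRUPTION_MODES[j % 3]) for j, idx in enumerate(indices)]

    with open(sdf_path) as fh:
        text = fh.read()
    entries = text.split("$$$$\n")
    if entries and entries[-1].strip() == "":
        entries = entries[:-1]
    for idx, mode in planted:
        lines = entries[idx].splitlines()
        if mode == "bad_counts":
            lines[3] = "xx corrupted counts line xx"
        elif mode == "truncated":
            lines = lines[: max(4, len(lines) // 2 - 3)]
        else:  # missing_annotation: drop the data-field block
            end = next(i for i, ln in enumerate(lines) if ln.startswith("M  END"))
            lines = lines[: end + 1]
        entries[idx] = "\n".join(lines) + "\n"
    with open(sdf_path, "w") as fh:
        fh.write("$$$$\n".join(entries) + "$$$$\n")
    return planted
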