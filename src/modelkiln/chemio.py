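"""Chemical structure I/O and annotation extraction.

Reads and writes multi-record SDFiles (V2000 connection tables plus named
data fields), normalizes structures, and turns an annotation field into the
Y vector of a training series.  The guiding rule throughout is *per-molecule
failure isolation*: a malformed entry never aborts a run — it yields a
record with ``status="failed"`` and a human-readable reason, and the
pipeline continues with the survivors.

Atom and bond indices are 0-based internally; the 1-based SDF convention is
converted at the file boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FatalError

__all__ = [
    "MoleculeRecord",
    "AnnotatedSeries",
    "read_sdf",
    "write_sdf",
    "normalize_structure",
    "extract_annotations",
    "read_tsv_table",
    "register_normalizer",
    "NORMALIZER_ADAPTERS",
]

# Old-style atom-block charge column codes (ctfile spec); superseded by M CHG.
_CHARGE_CODES = {0: 0, 1: 3, 2: 2, 3: 1, 4: 0, 5: -1, 6: -2, 7: -3}
_CHARGE_CODES_INV = {0: 0, 3: 1, 2: 2, 1: 3, -1: 5, -2: 6, -3: 7}


@dataclass
class MoleculeRecord:
    """One parsed structure with its named data fields.

    atoms are ``(element symbol, formal charge)`` pairs; bonds are
    ``(atom_i, atom_j, order)`` with 0-based endpoints.
    """

    name: str
    atoms: list = field(default_factory=list)
    bonds: list = field(default_factory=list)
    properties: dict = field(default_factory=dict)
    source_index: int = 0
    status: str = "ok"
    failure_reason: str = ""

    def fail(self, reason: str) -> "MoleculeRecord":
        """Return a copy flagged as failed with the given reason."""
        return replace(self, status="failed", failure_reason=reason)

    def validate(self) -> None:
        n = len(self.atoms)
        for a, b, _order in self.bonds:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond endpoint out of range: ({a},{b}) with {n} atoms")
        if self.status == "failed" and not self.failure_reason:
            raise ValueError("failed record without a failure reason")


@dataclass
class AnnotatedSeries:
    """Records plus the activity vector Y over the records that parsed ok."""

    records: list
    y: np.ndarray
    annotation_field: str
    endpoint_type: str  # "qualitative" | "quantitative"

    @property
    def ok_records(self) -> list:
        return [r for r in self.records if r.status == "ok"]


# ---------------------------------------------------------------------------
# SDF reading


def _split_entries(text: str) -> list:
    """Split SDF text into entries on ``$$$$`` delimiter lines."""
    entries, current = [], []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            entries.append(current)
            current = []
        else:
            current.append(line)
    if any(ln.strip() for ln in current):  # trailing entry without $$$$
        entries.append(current)
    return entries


def _parse_molblock(lines: list) -> tuple:
    """Parse one V2000 molblock; returns (name, atoms, bonds, body_end_index)."""
    if len(lines) < 4:
        raise ValueError("entry too short to contain a molblock")
    name = lines[0].strip()
    counts = lines[3]
    if "V3000" in counts:
        raise ValueError("V3000 connection tables are not supported")
    try:
        natoms = int(counts[0:3])
        nbonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise ValueError(f"corrupt counts line: {counts!r}")
    if natoms < 0 or nbonds < 0:
        raise ValueError(f"negative counts in counts line: {counts!r}")

    atom_lines = lines[4 : 4 + natoms]
    bond_lines = lines[4 + natoms : 4 + natoms + nbonds]
    if len(atom_lines) < natoms or len(bond_lines) < nbonds:
        raise ValueError("truncated atom or bond block")

    atoms = []
    for ln in atom_lines:
        element = ln[31:34].strip()
        if not element or not element[0].isalpha():
            raise ValueError(f"unreadable atom line: {ln!r}")
        charge = 0
        code_txt = ln[36:39].strip()
        if code_txt:
            charge = _CHARGE_CODES.get(int(code_txt), 0)
        atoms.append((element, charge))

    bonds = []
    for ln in bond_lines:
        try:
            a = int(ln[0:3]) - 1
            b = int(ln[3:6]) - 1
            order = int(ln[6:9])
        except (ValueError, IndexError):
            raise ValueError(f"unreadable bond line: {ln!r}")
        if not (0 <= a < natoms and 0 <= b < natoms):
            raise ValueError(f"bond references missing atom: {ln!r}")
        bonds.append((a, b, order))

    # Properties block: M CHG supersedes all atom-block charges.
    i = 4 + natoms + nbonds
    saw_chg = False
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("M  END"):
            i += 1
            break
        if ln.startswith("M  CHG"):
            if not saw_chg:
                atoms = [(el, 0) for el, _ in atoms]
                saw_chg = True
            fields = ln.split()
            npairs = int(fields[2])
            for k in range(npairs):
                idx = int(fields[3 + 2 * k]) - 1
                chg = int(fields[4 + 2 * k])
                if not 0 <= idx < natoms:
                    raise ValueError(f"M CHG references missing atom: {ln!r}")
                atoms[idx] = (atoms[idx][0], chg)
        i += 1
    return name, atoms, bonds, i


def _parse_data_fields(lines: list) -> dict:
    props: dict = {}
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.startswith(">"):
            lt, gt = ln.find("<"), ln.find(">", ln.find("<"))
            if lt == -1 or gt == -1:
                raise ValueError(f"malformed data header: {ln!r}")
            key = ln[lt + 1 : gt]
            i += 1
            values = []
            while i < len(lines) and lines[i].strip() != "":
                values.append(lines[i])
                i += 1
            props[key] = "\n".join(values)
        i += 1
    return props


def read_sdf(path) -> list:
    """Read an SDFile into MoleculeRecords, one per ``$$$$``-delimited entry.

    Unparseable entries become ``status="failed"`` records (with the parse
    error as the reason) instead of aborting; record order always matches
    file order.  An unreadable file is the only fatal condition.
    """
    try:
        with open(path, "r") as fh:
            text = fh.read()
    except OSError as exc:
        raise FatalError(f"cannot read structure file {path}: {exc}", stage="idata")

    entries = _split_entries(text)
    if not entries:
        warnings.warn(f"no entries found in {path}")
        return []

    records = []
    for idx, lines in enumerate(entries):
        fallback_name = lines[0].strip() if lines else ""
        try:
            name, atoms, bonds, end = _parse_molblock(lines)
            props = _parse_data_fields(lines[end:])
            rec = MoleculeRecord(
                name=name or f"mol_{idx}",
                atoms=atoms,
                bonds=bonds,
                properties=props,
                source_index=idx,
            )
            rec.validate()
        except (ValueError, IndexError) as exc:
            rec = MoleculeRecord(
                name=fallback_name or f"mol_{idx}",
                source_index=idx,
                status="failed",
                failure_reason=str(exc),
            )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# SDF writing


def write_sdf(records, path) -> None:
    """Write ok records as a V2000 SDFile re-readable by :func:`read_sdf`.

    Coordinates are written as zeros (the record model is a topological
    graph); charges are emitted as ``M  CHG`` lines.
    """
    out = []
    for rec in records:
        if rec.status != "ok":
            raise ValueError(f"cannot write failed record {rec.name!r}")
        out.append(rec.name)
        out.append("  modelkiln")
        out.append("")
        out.append(f"{len(rec.atoms):3d}{len(rec.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
        for element, _charge in rec.atoms:
            out.append(f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
        for a, b, order in rec.bonds:
            out.append(f"{a + 1:3d}{b + 1:3d}{order:3d}  0")
        charged = [(i, c) for i, (_el, c) in enumerate(rec.atoms) if c != 0]
        for start in range(0, len(charged), 8):
            chunk = charged[start : start + 8]
            line = f"M  CHG{len(chunk):3d}"
            for i, c in chunk:
                line += f"{i + 1:4d}{c:4d}"
            out.append(line)
        out.append("M  END")
        for key, value in rec.properties.items():
            out.append(f"> <{key}>")
            out.extend(value.split("\n"))
            out.append("")
        out.append("$$$$")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(out) + ("\n" if out else ""))
    except OSError as exc:
        raise FatalError(f"cannot write {path}: {exc}", stage="odata")


# ---------------------------------------------------------------------------
# Structure normalization

NORMALIZER_ADAPTERS: dict = {}


def register_normalizer(name: str, func: Callable) -> None:
    """Register an external normalization pipeline under ``name``.

    The adapter receives and returns a MoleculeRecord; raising flags the
    molecule as failed rather than aborting the run.
    """
    NORMALIZER_ADAPTERS[name] = func


def _components(n_atoms: int, bonds) -> list:
    """Connected components of the bond graph, as sorted atom-index lists."""
    parent = list(range(n_atoms))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in bonds:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for i in range(n_atoms):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def _largest_fragment(rec: MoleculeRecord) -> MoleculeRecord:
    comps = _components(len(rec.atoms), rec.bonds)
    if len(comps) <= 1:
        return rec

    def bonds_in(comp_set):
        return sum(1 for a, b, _ in rec.bonds if a in comp_set)

    # most atoms, then most bonds, then lowest first atom index
    best = max(
        comps,
        key=lambda c: (len(c), bonds_in(set(c)), -c[0]),
    )
    keep = set(best)
    remap = {old: new for new, old in enumerate(sorted(keep))}
    atoms = [rec.atoms[i] for i in sorted(keep)]
    bonds = [(remap[a], remap[b], o) for a, b, o in rec.bonds if a in keep and b in keep]
    return replace(rec, atoms=atoms, bonds=bonds)


def normalize_structure(rec: MoleculeRecord, method: str = "largest_fragment") -> MoleculeRecord:
    """Normalize one structure.

    ``none`` returns the record untouched; ``largest_fragment`` strips
    counterions/solvents by keeping the connected component with the most
    atoms (ties: more bonds, then lowest first-atom index).  Any other name
    dispatches to a registered adapter (e.g. an external standardizer
    pipeline).  Adapter failures flag the record, never abort.
    """
    if method == "none":
        return rec
    if rec.status != "ok":
        return rec
    if method == "largest_fragment":
        return _largest_fragment(rec)
    if method in NORMALIZER_ADAPTERS:
        try:
            out = NORMALIZER_ADAPTERS[method](rec)
            out.validate()
            return out
        except Exception as exc:  # noqa: BLE001 - failure isolation by design
            return rec.fail(f"normalizer {method!r} failed: {exc}")
    raise ConfigurationError(
        f"unknown normalization method {method!r}; "
        f"built-ins: none, largest_fragment; adapters: {sorted(NORMALIZER_ADAPTERS)}"
    )


# ---------------------------------------------------------------------------
# Annotations

DEFAULT_POSITIVE = ("1", "positive", "pos", "active", "true")
DEFAULT_NEGATIVE = ("0", "negative", "neg", "inactive", "false")


def extract_annotations(
    records,
    annotation_field: str,
    endpoint_type: str = "quantitative",
    positive_synonyms=DEFAULT_POSITIVE,
    negative_synonyms=DEFAULT_NEGATIVE,
) -> AnnotatedSeries:
    """Build the activity vector Y from a named SDF data field.

    Records lacking the field, or with values that do not parse (numeric for
    quantitative endpoints, a recognized class synonym for qualitative), are
    flagged failed.  Fewer than two usable annotated records is fatal.
    """
    if endpoint_type not in ("qualitative", "quantitative"):
        raise ConfigurationError(f"unknown endpoint type {endpoint_type!r}")
    pos = {s.strip().lower() for s in positive_synonyms}
    neg = {s.strip().lower() for s in negative_synonyms}

    out_records, y = [], []
    for rec in records:
        if rec.status != "ok":
            out_records.append(rec)
            continue
        raw = rec.properties.get(annotation_field)
        if raw is None:
            out_records.append(rec.fail(f"missing annotation field {annotation_field!r}"))
            continue
        value = raw.strip()
        if endpoint_type == "quantitative":
            try:
                v = float(value)
            except ValueError:
                out_records.append(rec.fail(f"annotation {value!r} is not numeric"))
                continue
            if not np.isfinite(v):
                out_records.append(rec.fail(f"annotation {value!r} is not finite"))
                continue
            y.append(v)
        else:
            key = value.lower()
            if key in pos:
                y.append(1.0)
            elif key in neg:
                y.append(0.0)
            else:
                out_records.append(rec.fail(f"annotation {value!r} matches no class synonym"))
                continue
        out_records.append(rec)

    if len(y) < 2:
        raise FatalError(
            f"series too small: only {len(y)} usable annotated records", stage="idata"
        )
    return AnnotatedSeries(
        records=out_records,
        y=np.asarray(y, dtype=float),
        annotation_field=annotation_field,
        endpoint_type=endpoint_type,
    )


# ---------------------------------------------------------------------------
# Pre-computed descriptor tables


def read_tsv_table(path, annotation_column: str, name_column: str | None = None):
    """Read a TSV of pre-computed descriptors plus an annotation column.

    The first column (or ``name_column``) holds compound names; every other
    non-annotation column must be numeric.  Rows with unparseable descriptor
    cells are excluded and reported, mirroring SDF failure isolation.

    Returns ``(DescriptorMatrix, y)``.
    """
    from .descriptors import DescriptorMatrix  # local import avoids a cycle

    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except OSError as exc:
        raise FatalError(f"cannot read table {path}: {exc}", stage="idata")
    if annotation_column not in df.columns:
        raise FatalError(
            f"annotation column {annotation_column!r} not found; "
            f"available columns: {list(df.columns)}",
            stage="idata",
        )
    name_column = name_column or df.columns[0]
    desc_cols = [c for c in df.columns if c not in (name_column, annotation_column)]
    if not desc_cols:
        raise FatalError("table contains no descriptor columns", stage="idata")

    rows, y, mask, failures = [], [], [], []
    for i, row in df.iterrows():
        try:
            values = [float(row[c]) for c in desc_cols]
            target = float(row[annotation_column])
            if not all(np.isfinite(v) for v in values) or not np.isfinite(target):
                raise ValueError("non-finite value")
        except (ValueError, TypeError):
            mask.append(False)
            failures.append((int(i), str(row[name_column]), "non-numeric or non-finite cell"))
            continue
        mask.append(True)
        rows.append(values)
        y.append(target)

    if not rows:
        raise FatalError("empty X matrix: every table row failed", stage="idata")
    ok_names = [str(df.iloc[i][name_column]) for i in range(len(df)) if mask[i]]
    dm = DescriptorMatrix(
        X=np.asarray(rows, dtype=float),
        names=desc_cols,
        row_ids=ok_names,
        success_mask=np.asarray(mask, dtype=bool),
        failures=failures,
    )
    return dm, np.asarray(y, dtype=float)
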