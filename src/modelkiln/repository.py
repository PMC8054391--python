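"""Model governance: versioned model folders, labels, IDs, export/import.

A model repository is a directory; each model is a folder named after the
model holding a mutable ``dev`` version plus immutable published versions
``ver000001, ver000002, ...``.  Every model is watermarked at creation
with a unique ID — a random string of ten uppercase ASCII letters — that
travels with exports and is stamped on every prediction, so provenance
survives renames and transfers between installations.

Published versions are made read-only on disk; the only way to change a
model is to rebuild ``dev`` and publish a new version.  Predictions are
kept in a persistent store inside the repository until actively deleted.
"""

from __future__ import annotations

import datetime
import io
import os
import random
import shutil
import stat
import string
import tarfile
import warnings
from pathlib import Path

import yaml

from . import __version__ as framework_version
from .errors import RepositoryError
from .learners import library_versions
from .params import ParameterSet

__all__ = ["ModelRepository", "new_model_id"]

META_FILE = "model-meta.yml"
DOC_FILE = "documentation.yml"
HOOK_FILE = "custom.py"
ARCHIVE_MANIFEST = "MANIFEST.yml"
ARCHIVE_SUFFIX = ".mkiln"

HOOK_TEMPLATE = '''"""Per-model code overrides."""

# Define any of these functions to replace the corresponding pipeline stage
# *for this model only*.  They travel with the model on export/import and
# run only when the repository enables model code (allow_model_code).
#
# def hook_normalize(records):
#     "Replace structure normalization; records in, records out."
#
# def hook_descriptors(records):
#     "Replace descriptor computation; must return a DescriptorMatrix."
#
# def hook_post_output(result):
#     "Post-process one per-compound output dict before it is written."
'''

DOC_SECTIONS = ("General Model information", "Algorithms", "Other information")

_DOC_TEMPLATE = {
    "General Model information": {
        "Model title": "",
        "Model description": "",
        "Endpoint": "",
        "Species": "",
        "Contact": "",
        "Date": "",
        "Interpretation": "",
    },
    "Algorithms": {},  # auto-completed at every build
    "Other information": {
        "License": "",
        "Comments": "",
    },
}


def new_model_id(rng: random.Random | None = None) -> str:
    """A fresh model watermark: exactly ten uppercase ASCII letters."""
    rng = rng or random.SystemRandom()
    return "".join(rng.choice(string.ascii_uppercase) for _ in range(10))


def _set_tree_writable(path: Path, writable: bool) -> None:
    dir_mode = 0o755 if writable else 0o555
    file_mode = 0o644 if writable else 0o444
    for root, dirs, files in os.walk(path, topdown=False):
        for f in files:
            os.chmod(Path(root) / f, file_mode)
        for d in dirs:
            os.chmod(Path(root) / d, dir_mode)
    os.chmod(path, dir_mode)


class ModelRepository:
    """A directory of model folders plus the persistent prediction store."""

    def __init__(self, path, allow_model_code: bool | None = None):
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)
        cfg = self._load_config()
        if allow_model_code is None:
            allow_model_code = bool(cfg.get("allow_model_code", False))
        self.allow_model_code = allow_model_code

    # -- config -------------------------------------------------------------

    @property
    def _config_path(self) -> Path:
        return self.path / "config.yml"

    def _load_config(self) -> dict:
        if self._config_path.exists():
            return yaml.safe_load(self._config_path.read_text()) or {}
        return {}

    def set_config(self, **kwargs) -> None:
        cfg = self._load_config()
        cfg.update(kwargs)
        self._config_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
        if "allow_model_code" in kwargs:
            self.allow_model_code = bool(kwargs["allow_model_code"])

    # -- paths --------------------------------------------------------------

    def model_dir(self, name: str) -> Path:
        return self.path / name

    @staticmethod
    def version_name(version) -> str:
        if version == "dev":
            return "dev"
        return f"ver{int(version):06d}"

    def version_dir(self, name: str, version) -> Path:
        d = self.model_dir(name) / self.version_name(version)
        if not d.exists():
            raise RepositoryError(f"model {name!r} has no version {version!r}")
        return d

    def model_exists(self, name: str) -> bool:
        return (self.model_dir(name) / META_FILE).exists()

    # -- metadata -----------------------------------------------------------

    def load_meta(self, name: str) -> dict:
        meta_path = self.model_dir(name) / META_FILE
        if not meta_path.exists():
            raise RepositoryError(f"no model named {name!r} in repository {self.path}")
        return yaml.safe_load(meta_path.read_text())

    def _save_meta(self, name: str, meta: dict) -> None:
        (self.model_dir(name) / META_FILE).write_text(
            yaml.safe_dump(meta, sort_keys=True)
        )

    def unique_id(self, name: str) -> str:
        return self.load_meta(name)["unique_id"]

    def published_versions(self, name: str) -> list:
        self.load_meta(name)
        out = []
        for child in sorted(self.model_dir(name).iterdir()):
            if child.is_dir() and child.name.startswith("ver"):
                out.append(int(child.name[3:]))
        return out

    # -- model lifecycle ----------------------------------------------------

    def new_model(self, name: str, labels: dict | None = None, rng=None) -> Path:
        """Scaffold a model: dev folder, default blueprint, hook template, ID."""
        if self.model_exists(name):
            raise RepositoryError(f"model {name!r} already exists")
        dev = self.model_dir(name) / "dev"
        dev.mkdir(parents=True)
        params = ParameterSet()
        if labels:
            params.update({"labels": labels})
        params.save(dev / ParameterSet.FILENAME)
        (dev / HOOK_FILE).write_text(HOOK_TEMPLATE)
        meta = {
            "name": name,
            "unique_id": new_model_id(rng),
            "labels": dict(params.get("labels")),
            "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
        self._save_meta(name, meta)
        return self.model_dir(name)

    def publish(self, name: str) -> int:
        """Freeze the current dev build as the next immutable version."""
        dev = self.version_dir(name, "dev")
        if not (dev / "estimator.bin").exists():
            raise RepositoryError(
                f"model {name!r} has no completed dev build to publish"
            )
        version = (self.published_versions(name) or [0])[-1] + 1
        target = self.model_dir(name) / self.version_name(version)
        shutil.copytree(dev, target)
        _set_tree_writable(target, writable=False)
        return version

    def write_artifact(self, name: str, version, filename: str, data) -> None:
        """Write a file into a model version; refused for published versions.

        Published folders are additionally made read-only on disk, but this
        API-level guard holds regardless of filesystem privileges.
        """
        if version != "dev":
            raise RepositoryError(
                f"version {version} of {name!r} is published and immutable; "
                "rebuild dev and publish a new version instead"
            )
        target = self.version_dir(name, version) / filename
        mode = "wb" if isinstance(data, bytes) else "w"
        with open(target, mode) as fh:
            fh.write(data)

    def remove(self, name: str, version=None) -> None:
        """Delete one published version, or the whole model tree."""
        if version is None or version == "all":
            target = self.model_dir(name)
            if not target.exists():
                raise RepositoryError(f"no model named {name!r}")
        else:
            target = self.version_dir(name, version)
        _set_tree_writable(target, writable=True)
        shutil.rmtree(target)

    def list_models(self, labels: dict | None = None, text: str | None = None) -> list:
        """Sortable model summaries, filterable by label values and name text."""
        out = []
        for child in sorted(self.path.iterdir()):
            if not (child.is_dir() and (child / META_FILE).exists()):
                continue
            meta = self.load_meta(child.name)
            if text and text.lower() not in meta["name"].lower():
                continue
            if labels and any(
                str(meta.get("labels", {}).get(k, "")).lower() != str(v).lower()
                for k, v in labels.items()
            ):
                continue
            out.append(
                {
                    "name": meta["name"],
                    "unique_id": meta["unique_id"],
                    "labels": meta.get("labels", {}),
                    "versions": self.published_versions(child.name),
                    "endpoint": meta.get("labels", {}).get("Endpoint", ""),
                }
            )
        return out

    def set_labels(self, name: str, labels: dict) -> None:
        meta = self.load_meta(name)
        meta.setdefault("labels", {}).update(labels)
        self._save_meta(name, meta)

    # -- export / import -----------------------------------------------------

    def export_model(self, name: str, out_path=None) -> Path:
        """Pack the whole model folder (all versions, hooks, docs) into one file."""
        meta = self.load_meta(name)
        out_path = Path(out_path) if out_path else Path.cwd() / f"{name}{ARCHIVE_SUFFIX}"
        estimator_manifests = {}
        for child in sorted(self.model_dir(name).iterdir()):
            mf = child / "estimator.manifest"
            if mf.exists():
                estimator_manifests[child.name] = yaml.safe_load(mf.read_text())
        manifest = {
            "framework_version": framework_version,
            "name": name,
            "unique_id": meta["unique_id"],
            "versions": ["dev"] + [f"ver{v:06d}" for v in self.published_versions(name)],
            "estimator_manifests": estimator_manifests,
        }
        manifest_text = yaml.safe_dump(manifest, sort_keys=True)
        with tarfile.open(out_path, "w:gz") as tar:
            info = tarfile.TarInfo(ARCHIVE_MANIFEST)
            data = manifest_text.encode()
            info.size = len(data)
            tar.addfile(info, io.BytesIO(data))
            tar.add(self.model_dir(name), arcname=name)
        return out_path

    def import_model(self, archive, rename: str | None = None) -> str:
        """Install a model archive; returns the installed model name.

        Library-version mismatches between the archive's estimator
        manifests and the current environment warn but never block the
        import; predictions are only guaranteed identical when versions
        match.  A name collision is refused — pass ``rename`` to install
        under a different name (the unique ID still identifies the origin).
        """
        archive = Path(archive)
        try:
            with tarfile.open(archive, "r:gz") as tar:
                names = tar.getnames()
                if ARCHIVE_MANIFEST not in names:
                    raise RepositoryError(
                        f"{archive} is not a model archive: missing {ARCHIVE_MANIFEST}"
                    )
                manifest = yaml.safe_load(
                    tar.extractfile(ARCHIVE_MANIFEST).read().decode()
                )
                src_name = manifest["name"]
                dest_name = rename or src_name
                if self.model_exists(dest_name):
                    raise RepositoryError(
                        f"model {dest_name!r} already exists; "
                        "pass rename=<new name> to install under another name"
                    )
                members = [m for m in tar.getmembers() if m.name.startswith(src_name + "/")]
                staging = self.path / f".import-{os.getpid()}"
                if staging.exists():
                    shutil.rmtree(staging)
                staging.mkdir()
                tar.extractall(staging, members=members, filter="data")
        except (tarfile.TarError, OSError, KeyError) as exc:
            raise RepositoryError(f"cannot import {archive}: {exc}")

        (staging / src_name).rename(self.path / dest_name)
        shutil.rmtree(staging)
        _set_tree_writable(self.model_dir(dest_name), writable=True)
        meta = self.load_meta(dest_name)
        meta["name"] = dest_name
        self._save_meta(dest_name, meta)

        current = library_versions()
        for ver, mf in (manifest.get("estimator_manifests") or {}).items():
            recorded = (mf or {}).get("library_versions", {})
            for lib, ver_str in recorded.items():
                if lib in current and current[lib] != ver_str:
                    warnings.warn(
                        f"library version mismatch for imported model "
                        f"{dest_name!r} ({ver}): {lib} {ver_str} (archive) vs "
                        f"{current[lib]} (current); predictions may differ"
                    )
        hook_path = self.model_dir(dest_name) / "dev" / HOOK_FILE
        if hook_path.exists() and hook_path.read_text() != HOOK_TEMPLATE:
            warnings.warn(
                f"imported model {dest_name!r} carries custom per-model code; "
                f"it runs only if this repository sets allow_model_code"
            )
        return dest_name

    # -- documentation -------------------------------------------------------

    def document_model(self, name: str, version="dev", yaml_in=None) -> dict:
        """Load, optionally merge, and return a version's documentation.

        The three-section template (General Model information / Algorithms /
        Other information) is auto-completed at build time in its Algorithms
        section; ``yaml_in`` (path or text) merges into the *user* sections
        only, leaving auto-filled fields untouched.
        """
        vdir = self.version_dir(name, version)
        doc_path = vdir / DOC_FILE
        if doc_path.exists():
            doc = yaml.safe_load(doc_path.read_text())
        else:
            doc = {k: dict(v) for k, v in _DOC_TEMPLATE.items()}
        if yaml_in is not None:
            text = (
                Path(yaml_in).read_text()
                if isinstance(yaml_in, (str, Path)) and Path(str(yaml_in)).exists()
                else str(yaml_in)
            )
            try:
                incoming = yaml.safe_load(text)
            except yaml.YAMLError as exc:
                raise RepositoryError(f"malformed documentation yaml: {exc}")
            if not isinstance(incoming, dict):
                raise RepositoryError("documentation yaml must be a mapping of sections")
            for section, block in incoming.items():
                if section not in DOC_SECTIONS:
                    raise RepositoryError(
                        f"unknown documentation section {section!r}; "
                        f"expected one of {list(DOC_SECTIONS)}"
                    )
                if section == "Algorithms":
                    continue  # auto-filled; user input never overrides it
                doc.setdefault(section, {}).update(block or {})
            self._write_doc(vdir, doc)
        return doc

    @staticmethod
    def _write_doc(vdir: Path, doc: dict) -> None:
        (vdir / DOC_FILE).write_text(yaml.safe_dump(doc, sort_keys=True))

    def autofill_documentation(self, name: str, params: ParameterSet, report) -> None:
        """Complete the Algorithms section of dev from the build just run."""
        vdir = self.version_dir(name, "dev")
        doc_path = vdir / DOC_FILE
        doc = (
            yaml.safe_load(doc_path.read_text())
            if doc_path.exists()
            else {k: dict(v) for k, v in _DOC_TEMPLATE.items()}
        )
        algo = {
            "normalization": params.get("normalization.method"),
            "descriptor_method": params.get("descriptors.method"),
            "scaling": params.get("descriptors.scaling"),
            "learner_method": params.get("learner.method"),
            "hyperparameters": params.get("learner.hyperparameters"),
            "conformal_enabled": params.get("conformal.enabled"),
            "conformal_confidence": params.get("conformal.confidence"),
            "cv_folds": report.folds,
            "endpoint_type": report.endpoint_type,
            "n_training": report.n_used,
            "quality_summary": report.to_dict()["display"],
        }
        doc["Algorithms"] = algo
        self._write_doc(vdir, doc)

    # -- prediction store ----------------------------------------------------

    @property
    def _pred_dir(self) -> Path:
        return self.path / ".predictions"

    def store_prediction(self, record) -> str:
        """Persist a prediction; returns its repository id."""
        self._pred_dir.mkdir(exist_ok=True)
        existing = sorted(self._pred_dir.glob("pred_*.yml"))
        next_id = 1 + (int(existing[-1].stem.split("_")[1]) if existing else 0)
        pred_id = f"pred_{next_id:06d}"
        payload = record.to_dict() if hasattr(record, "to_dict") else dict(record)
        (self._pred_dir / f"{pred_id}.yml").write_text(
            yaml.safe_dump(payload, sort_keys=True)
        )
        return pred_id

    def list_predictions(self) -> list:
        if not self._pred_dir.exists():
            return []
        out = []
        for p in sorted(self._pred_dir.glob("pred_*.yml")):
            d = yaml.safe_load(p.read_text())
            header = d.get("header", d)
            out.append(
                {
                    "id": p.stem,
                    "model_name": header.get("model_name"),
                    "unique_id": header.get("unique_id"),
                    "version": header.get("version"),
                    "timestamp": header.get("timestamp"),
                }
            )
        return out

    def get_prediction(self, pred_id: str) -> dict:
        p = self._pred_dir / f"{pred_id}.yml"
        if not p.exists():
            raise RepositoryError(f"unknown prediction id {pred_id!r}")
        return yaml.safe_load(p.read_text())

    def delete_prediction(self, pred_id: str) -> None:
        p = self._pred_dir / f"{pred_id}.yml"
        if not p.exists():
            raise RepositoryError(f"unknown prediction id {pred_id!r}")
        p.unlink()

    def resolve_prediction_model(self, pred_id: str) -> dict:
        """Trace a stored prediction back to its generating model by unique ID."""
        d = self.get_prediction(pred_id)
        header = d.get("header", d)
        uid, version = header.get("unique_id"), header.get("version")
        for summary in self.list_models():
            if summary["unique_id"] == uid:
                present = version in summary["versions"]
                return {
                    "model_name": summary["name"],
                    "unique_id": uid,
                    "version": version,
                    "status": "present" if present else "version deleted",
                }
        return {
            "model_name": header.get("model_name"),
            "unique_id": uid,
            "version": version,
            "status": "model deleted",
        }
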