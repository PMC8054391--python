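"""Build/predict orchestration: artifacts, code sharing, hooks, failures."""

import json

import numpy as np
import pytest
import yaml

from modelkiln import workflows
from modelkiln.descriptors import DescriptorMatrix
from modelkiln.errors import FatalError
from modelkiln.fixtures import FixtureSpec, generate_malformed, generate_series
from modelkiln.params import ParameterSet
from modelkiln.repository import HOOK_FILE, ModelRepository


def make_repo(tmp_path, name="m1", **repo_kwargs):
    repo = ModelRepository(tmp_path / "repo", **repo_kwargs)
    if not repo.model_exists(name):
        repo.new_model(name)
    return repo


def test_build_persists_all_artifacts(built_repo):
    dev = built_repo["repo"].version_dir("acme", "dev")
    for artifact in (
        "estimator.bin",
        "estimator.manifest",
        "model-results.yaml",
        "parameters.yml",
        "scaler.json",
        "space.json",
        "training.json",
        "training_input.sdf",
        "documentation.yml",
    ):
        assert (dev / artifact).exists(), artifact


def test_default_validation_is_five_fold(built_repo):
    assert built_repo["report"].folds == 5
    saved = yaml.safe_load(
        (built_repo["repo"].version_dir("acme", "dev") / "model-results.yaml").read_text()
    )
    assert saved["folds"] == 5


def test_estimator_manifest_records_provenance(built_repo):
    manifest = yaml.safe_load(
        (built_repo["repo"].version_dir("acme", "dev") / "estimator.manifest").read_text()
    )
    assert manifest["method"] == "RF"
    assert manifest["seed"] == 46
    assert "scikit-learn" in manifest["library_versions"]


def test_rebuild_replaces_previous_dev(tmp_path, series_paths):
    repo = make_repo(tmp_path)
    workflows.build(repo, "m1", series_paths[0], ["annotation.field=activity"])
    first = (repo.version_dir("m1", "dev") / "model-results.yaml").read_bytes()
    workflows.build(
        repo, "m1", series_paths[0],
        ["annotation.field=activity", "learner.method=PLS"],
    )
    dev = repo.version_dir("m1", "dev")
    assert (dev / "model-results.yaml").read_bytes() != first
    assert ParameterSet.load(dev).get("learner.method") == "PLS"


def test_failed_molecules_isolated_and_reported(tmp_path):
    sdf = tmp_path / "series.sdf"
    planted = generate_malformed(FixtureSpec(n=60, seed=9, noise_sd=0.2), 3, sdf)
    repo = make_repo(tmp_path)
    report = workflows.build(repo, "m1", sdf, ["annotation.field=activity"])
    assert report.n_used == 57
    assert sorted(f[0] for f in report.failures) == sorted(i for i, _m in planted)


def test_predict_with_dev_version_refused(built_repo):
    with pytest.raises(FatalError, match="dev version cannot be used"):
        workflows.predict(built_repo["repo"], "acme", "dev", built_repo["sdf"])


def test_noiseless_model_recovers_training_values(tmp_path):
    sdf = tmp_path / "clean.sdf"
    generate_series(FixtureSpec(n=40, seed=2, noise_sd=0.0), sdf, tmp_path / "t.tsv")
    repo = make_repo(tmp_path)
    workflows.build(
        repo, "m1", sdf,
        ["annotation.field=activity", "learner.method=PLS", "conformal.enabled=false"],
    )
    v = repo.publish("m1")
    record = workflows.predict(repo, "m1", v, sdf)
    lines = (tmp_path / "t.tsv").read_text().splitlines()
    start = next(i for i, ln in enumerate(lines) if ln.startswith("name\t")) + 1
    truth = [float(line.split("\t")[1]) for line in lines[start:]]
    predicted = [c["value"] for c in record.compounds]
    assert np.allclose(predicted, truth, atol=0.15)


def test_build_and_predict_share_descriptor_rows(built_repo):
    """The X row of a molecule is bit-identical between build and predict."""
    repo, sdf = built_repo["repo"], built_repo["sdf"]
    vdir = repo.version_dir("acme", built_repo["version"])
    stored = np.asarray(json.load(open(vdir / "training.json"))["X_scaled"])
    params = ParameterSet.load(vdir)
    records = workflows._prepare_records(sdf, params, workflows.Hooks())
    dm = workflows._compute_matrix(records, params, workflows.Hooks(), None, None)
    from modelkiln.descriptors import apply_scaler

    X = apply_scaler(dm.X, workflows._load_scaler(vdir / "scaler.json"))
    assert np.array_equal(X, stored)


def test_confidence_override_leaves_stored_state(built_repo):
    repo, v, sdf = built_repo["repo"], built_repo["version"], built_repo["sdf"]
    narrow = workflows.predict(repo, "acme", v, sdf, confidence=0.7)
    wide = workflows.predict(repo, "acme", v, sdf, confidence=0.95)
    w_narrow = np.mean([c["y_max"] - c["y_min"] for c in narrow.compounds])
    w_wide = np.mean([c["y_max"] - c["y_min"] for c in wide.compounds])
    assert w_narrow < w_wide
    assert ParameterSet.load(repo.version_dir("acme", v)).get("conformal.confidence") == 0.8


def test_duplicate_structures_surface_in_report(tmp_path, series_paths):
    from modelkiln.chemio import read_sdf, write_sdf

    records = read_sdf(series_paths[0])
    doubled = records + [records[0]]
    sdf = tmp_path / "dup.sdf"
    write_sdf(doubled, sdf)
    repo = make_repo(tmp_path)
    report = workflows.build(repo, "m1", sdf, ["annotation.field=activity"])
    assert any(records[0].name in group for group in report.duplicates)


def test_tsv_input_builds_model(tmp_path):
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 3))
    y = X @ np.array([1.0, -2.0, 0.5])
    lines = ["name\td1\td2\td3\tact"] + [
        f"m{i}\t{float(X[i,0])!r}\t{float(X[i,1])!r}\t{float(X[i,2])!r}\t{float(y[i])!r}"
        for i in range(40)
    ]
    tsv = tmp_path / "table.tsv"
    tsv.write_text("\n".join(lines) + "\n")
    repo = make_repo(tmp_path)
    report = workflows.build(
        repo, "m1", tsv,
        ["annotation.field=act", "learner.method=PLS", "conformal.enabled=false",
         "learner.hyperparameters={n_components: 3}"],
    )
    assert report.prediction["q2"] > 0.99


class TestHooks:
    CONSTANT_HOOK = (
        "import numpy as np\n"
        "from modelkiln.descriptors import DescriptorMatrix\n"
        "def hook_descriptors(records):\n"
        "    ok = [r for r in records if r.status == 'ok']\n"
        "    X = np.array([[float(len(r.atoms)), 1.0] for r in ok])\n"
        "    return DescriptorMatrix(X=X, names=['n_atoms', 'const'],\n"
        "        row_ids=[r.name for r in ok],\n"
        "        success_mask=np.array([r.status == 'ok' for r in records]))\n"
    )

    def test_absent_hooks_equal_defaults(self, tmp_path, series_paths):
        repo = make_repo(tmp_path, allow_model_code=True)
        report = workflows.build(repo, "m1", series_paths[0], ["annotation.field=activity"])
        assert report.n_used == 60  # template file defines no hooks

    def test_hooks_ignored_with_warning_when_disabled(self, tmp_path, series_paths):
        repo = make_repo(tmp_path, allow_model_code=False)
        dev = repo.version_dir("m1", "dev")
        (dev / HOOK_FILE).write_text(self.CONSTANT_HOOK)
        with pytest.warns(UserWarning, match="allow_model_code"):
            report = workflows.build(repo, "m1", series_paths[0], ["annotation.field=activity"])
        assert report.chemspace["scores"]  # built with default descriptors

    def test_hook_replaces_descriptor_stage_for_this_model_only(self, tmp_path, series_paths):
        repo = make_repo(tmp_path, "hooked", allow_model_code=True)
        repo.new_model("plain")
        (repo.version_dir("hooked", "dev") / HOOK_FILE).write_text(self.CONSTANT_HOOK)
        hooked = workflows.build(repo, "hooked", series_paths[0], ["annotation.field=activity"])
        plain = workflows.build(repo, "plain", series_paths[0], ["annotation.field=activity"])
        vdirs = [repo.version_dir(n, "dev") / "training.json" for n in ("hooked", "plain")]
        cols = [len(json.load(open(p))["names"]) for p in vdirs]
        assert cols[0] == 2 and cols[1] > 2
        assert hooked.n_used == plain.n_used == 60

    def test_hook_travels_with_export(self, tmp_path, series_paths):
        repo = make_repo(tmp_path, allow_model_code=True)
        (repo.version_dir("m1", "dev") / HOOK_FILE).write_text(self.CONSTANT_HOOK)
        workflows.build(repo, "m1", series_paths[0], ["annotation.field=activity"])
        v = repo.publish("m1")
        archive = repo.export_model("m1", tmp_path / "m1.mkiln")
        dest = ModelRepository(tmp_path / "dest", allow_model_code=True)
        with pytest.warns(UserWarning, match="custom per-model code"):
            dest.import_model(archive)
        record = workflows.predict(dest, "m1", v, series_paths[0])
        origin = workflows.predict(repo, "m1", v, series_paths[0])
        assert record.payload_canonical() == origin.payload_canonical()

    def test_raising_hook_aborts_with_stage_tag(self, tmp_path, series_paths):
        repo = make_repo(tmp_path, allow_model_code=True)
        (repo.version_dir("m1", "dev") / HOOK_FILE).write_text(
            "def hook_normalize(records):\n    raise RuntimeError('bad hook')\n"
        )
        with pytest.raises(FatalError, match="hook.*normalize.*bad hook"):
            workflows.build(repo, "m1", series_paths[0], ["annotation.field=activity"])
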