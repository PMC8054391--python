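"""Model governance: IDs, versions, immutability, export/import, predictions."""

import random
import re
import tarfile

import pytest
import yaml

from modelkiln import workflows
from modelkiln.errors import RepositoryError
from modelkiln.repository import ARCHIVE_MANIFEST, ModelRepository, new_model_id


class TestModelIds:
    def test_id_charset_and_length(self):
        rng = random.Random(7)
        pattern = re.compile(r"^[A-Z]{10}$")
        assert all(pattern.match(new_model_id(rng)) for _ in range(500))

    def test_same_name_distinct_repositories_distinct_ids(self, tmp_path):
        a = ModelRepository(tmp_path / "a")
        b = ModelRepository(tmp_path / "b")
        a.new_model("caco2", rng=random.Random(1))
        b.new_model("caco2", rng=random.Random(2))
        assert a.unique_id("caco2") != b.unique_id("caco2")


class TestLifecycle:
    def test_new_model_scaffold(self, tmp_path):
        repo = ModelRepository(tmp_path / "r")
        folder = repo.new_model("caco2")
        assert (folder / "dev" / "parameters.yml").exists()
        assert (folder / "dev" / "custom.py").exists()
        assert re.match(r"^[A-Z]{10}$", repo.unique_id("caco2"))

    def test_name_collision_refused(self, tmp_path):
        repo = ModelRepository(tmp_path / "r")
        repo.new_model("m")
        with pytest.raises(RepositoryError, match="already exists"):
            repo.new_model("m")

    def test_publish_requires_a_build(self, tmp_path):
        repo = ModelRepository(tmp_path / "r")
        repo.new_model("m")
        with pytest.raises(RepositoryError, match="no completed dev build"):
            repo.publish("m")

    def test_sequential_versions_and_selective_removal(self, tmp_path, series_paths):
        repo = ModelRepository(tmp_path / "r")
        repo.new_model("m")
        workflows.build(repo, "m", series_paths[0], ["annotation.field=activity"])
        assert repo.publish("m") == 1
        assert repo.publish("m") == 2
        repo.remove("m", 1)
        assert repo.published_versions("m") == [2]
        repo.version_dir("m", 2)  # still addressable
        with pytest.raises(RepositoryError):
            repo.version_dir("m", 1)

    def test_published_version_is_immutable(self, built_repo):
        repo, v = built_repo["repo"], built_repo["version"]
        with pytest.raises(RepositoryError, match="immutable"):
            repo.write_artifact("acme", v, "parameters.yml", "tampered")
        # on-disk permissions stripped as well (effective for non-root users)
        mode = (repo.version_dir("acme", v) / "parameters.yml").stat().st_mode
        assert not mode & 0o222


class TestListing:
    def test_filters_and_search(self, tmp_path):
        repo = ModelRepository(tmp_path / "r")
        repo.new_model("herg-rat", labels={"Species": "rat"})
        repo.new_model("caco2", labels={"Species": "human"})
        assert [m["name"] for m in repo.list_models(labels={"Species": "rat"})] == ["herg-rat"]
        assert [m["name"] for m in repo.list_models(text="CACO")] == ["caco2"]
        assert ModelRepository(tmp_path / "empty").list_models() == []


class TestExportImport:
    def test_round_trip_predictions_identical(self, tmp_path, built_repo):
        repo, v, sdf = built_repo["repo"], built_repo["version"], built_repo["sdf"]
        archive = repo.export_model("acme", tmp_path / "acme.mkiln")
        dest = ModelRepository(tmp_path / "fresh")
        dest.import_model(archive)
        origin = workflows.predict(repo, "acme", v, sdf)
        imported = workflows.predict(dest, "acme", v, sdf)
        assert imported.payload_canonical() == origin.payload_canonical()
        assert imported.header["unique_id"] == origin.header["unique_id"]

    def test_reexport_is_content_identical(self, tmp_path, built_repo):
        repo = built_repo["repo"]
        archive = repo.export_model("acme", tmp_path / "a.mkiln")
        dest = ModelRepository(tmp_path / "fresh2")
        dest.import_model(archive)
        names = set()
        for d in (repo.model_dir("acme"), dest.model_dir("acme")):
            names.add(
                tuple(sorted(p.relative_to(d).as_posix() for p in d.rglob("*") if p.is_file()))
            )
        assert len(names) == 1

    def test_version_mismatch_warns_but_installs(self, tmp_path, built_repo):
        archive = built_repo["repo"].export_model("acme", tmp_path / "a.mkiln")
        mutated = tmp_path / "mutated.mkiln"
        with tarfile.open(archive, "r:gz") as src, tarfile.open(mutated, "w:gz") as dst:
            for member in src.getmembers():
                data = src.extractfile(member) if member.isfile() else None
                if member.name == ARCHIVE_MANIFEST:
                    manifest = yaml.safe_load(data.read().decode())
                    for mf in manifest["estimator_manifests"].values():
                        mf["library_versions"]["scikit-learn"] = "0.0.1"
                    blob = yaml.safe_dump(manifest).encode()
                    member.size = len(blob)
                    import io

                    dst.addfile(member, io.BytesIO(blob))
                elif data is not None:
                    dst.addfile(member, data)
                else:
                    dst.addfile(member)
        dest = ModelRepository(tmp_path / "mismatch")
        with pytest.warns(UserWarning, match="version mismatch"):
            name = dest.import_model(mutated)
        assert dest.model_exists(name)

    def test_collision_refused_and_rename_offered(self, tmp_path, built_repo):
        repo = built_repo["repo"]
        archive = repo.export_model("acme", tmp_path / "a.mkiln")
        with pytest.raises(RepositoryError, match="rename"):
            repo.import_model(archive)
        name = repo.import_model(archive, rename="acme-copy")
        assert name == "acme-copy"
        assert repo.unique_id("acme-copy") == repo.unique_id("acme")
        repo.remove("acme-copy")

    def test_foreign_archive_rejected(self, tmp_path):
        bogus = tmp_path / "bogus.mkiln"
        bogus.write_bytes(b"not a tar archive")
        with pytest.raises(RepositoryError):
            ModelRepository(tmp_path / "r").import_model(bogus)


class TestPredictionStore:
    def test_store_survives_reopen_and_delete_removes(self, tmp_path, built_repo):
        repo, v, sdf = built_repo["repo"], built_repo["version"], built_repo["sdf"]
        record = workflows.predict(repo, "acme", v, sdf)
        pred_id = repo.store_prediction(record)
        reopened = ModelRepository(repo.path)
        listed = {p["id"] for p in reopened.list_predictions()}
        assert pred_id in listed
        stored = reopened.get_prediction(pred_id)
        assert stored["header"]["unique_id"] == record.header["unique_id"]
        reopened.delete_prediction(pred_id)
        assert pred_id not in {p["id"] for p in reopened.list_predictions()}
        with pytest.raises(RepositoryError):
            reopened.get_prediction(pred_id)

    def test_traceability_by_unique_id(self, tmp_path, series_paths):
        repo = ModelRepository(tmp_path / "r")
        repo.new_model("m")
        workflows.build(repo, "m", series_paths[0], ["annotation.field=activity"])
        v = repo.publish("m")
        record = workflows.predict(repo, "m", v, series_paths[0])
        pred_id = repo.store_prediction(record)
        assert repo.resolve_prediction_model(pred_id)["status"] == "present"
        repo.remove("m")
        assert repo.resolve_prediction_model(pred_id)["status"] == "model deleted"


class TestDocumentation:
    def test_algorithms_autofilled_from_build(self, built_repo):
        doc = built_repo["repo"].document_model("acme", "dev")
        algo = doc["Algorithms"]
        assert algo["descriptor_method"] == "composition"
        assert algo["cv_folds"] == 5
        assert algo["learner_method"] == "RF"

    def test_user_sections_merge_without_touching_auto(self, tmp_path, series_paths):
        repo = ModelRepository(tmp_path / "r")
        repo.new_model("m")
        workflows.build(repo, "m", series_paths[0], ["annotation.field=activity"])
        user_yaml = yaml.safe_dump(
            {
                "General Model information": {"Model title": "caco-2 permeability"},
                "Algorithms": {"learner_method": "HACKED"},
            }
        )
        doc = repo.document_model("m", "dev", user_yaml)
        assert doc["General Model information"]["Model title"] == "caco-2 permeability"
        assert doc["Algorithms"]["learner_method"] == "RF"

    def test_documentation_round_trip_lossless(self, tmp_path, series_paths):
        repo = ModelRepository(tmp_path / "r")
        repo.new_model("m")
        workflows.build(repo, "m", series_paths[0], ["annotation.field=activity"])
        doc1 = repo.document_model("m", "dev")
        text = yaml.safe_dump(
            {k: v for k, v in doc1.items() if k != "Algorithms"}, sort_keys=True
        )
        doc2 = repo.document_model("m", "dev", text)
        assert doc2 == doc1

    def test_malformed_document_rejected(self, built_repo):
        with pytest.raises(RepositoryError, match="malformed|unknown"):
            built_repo["repo"].document_model("acme", "dev", "a: [unclosed")
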