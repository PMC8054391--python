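"""Ensemble models: member matrices, combination rules, per-member detail."""

import numpy as np
import pytest

from modelkiln import workflows
from modelkiln.ensembles import INCONCLUSIVE, combine, ensemble_matrix
from modelkiln.errors import ConfigurationError, FatalError
from modelkiln.fixtures import FixtureSpec, generate_series
from modelkiln.repository import ModelRepository


@pytest.fixture(scope="module")
def ensemble_repo(tmp_path_factory):
    """Two published quantitative members + input series, shared by tests."""
    tmp = tmp_path_factory.mktemp("ens")
    sdf = tmp / "train.sdf"
    generate_series(FixtureSpec(n=60, seed=21, noise_sd=0.3), sdf, tmp / "t.tsv")
    repo = ModelRepository(tmp / "repo")
    for name, method in (("rf-member", "RF"), ("pls-member", "PLS")):
        repo.new_model(name)
        workflows.build(
            repo, name, sdf, ["annotation.field=activity", f"learner.method={method}"]
        )
        repo.publish(name)
    return {"repo": repo, "sdf": sdf, "members": [["rf-member", 1], ["pls-member", 1]]}


@pytest.fixture(scope="module")
def qualitative_repo(tmp_path_factory):
    """Three published conformal binary classifiers on one series."""
    tmp = tmp_path_factory.mktemp("qens")
    sdf = tmp / "train.sdf"
    generate_series(
        FixtureSpec(n=80, seed=33, noise_sd=0.5, endpoint_type="qualitative"),
        sdf, tmp / "t.tsv",
    )
    repo = ModelRepository(tmp / "repo")
    for i, seed in enumerate((1, 2, 3)):
        name = f"clf{i}"
        repo.new_model(name)
        workflows.build(
            repo, name, sdf,
            ["annotation.field=activity", "annotation.endpoint_type=qualitative",
             f"learner.seed={seed}"],
        )
        repo.publish(name)
    return {"repo": repo, "sdf": sdf, "members": [[f"clf{i}", 1] for i in range(3)]}


class TestCombine:
    def test_majority(self):
        assert combine([1, 1, 0], "majority", "qualitative") == 1
        assert combine([0, 0, 1], "majority", "qualitative") == 0

    def test_exact_tie_is_inconclusive(self):
        assert combine([1, 0], "majority", "qualitative") == INCONCLUSIVE

    def test_mean_and_median(self):
        assert combine([1.0, 2.0, 9.0], "median") == 2.0
        assert combine([1.0, 2.0, 9.0], "mean") == pytest.approx(4.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        values = list(rng.normal(size=5))
        for comb in ("mean", "median"):
            base = combine(values, comb)
            for _ in range(5):
                rng.shuffle(values)
                assert combine(values, comb) == base

    def test_unknown_combination_rejected(self):
        with pytest.raises(ConfigurationError):
            combine([1.0], "mode")


class TestEnsembleMatrix:
    def test_columns_equal_standalone_member_predictions(self, ensemble_repo):
        repo, sdf, members = (
            ensemble_repo["repo"], ensemble_repo["sdf"], ensemble_repo["members"],
        )
        dm, _ = ensemble_matrix(repo, [tuple(m) for m in members], sdf)
        assert dm.X.shape == (60, 2)
        for j, (name, version) in enumerate(members):
            standalone = workflows.predict(repo, name, version, sdf)
            values = [c["value"] for c in standalone.compounds if c["status"] == "ok"]
            assert np.array_equal(dm.X[:, j], np.asarray(values))

    def test_missing_member_is_fatal_and_named(self, ensemble_repo):
        with pytest.raises(FatalError, match="ghost"):
            ensemble_matrix(ensemble_repo["repo"], [("ghost", 1), ("rf-member", 1)],
                            ensemble_repo["sdf"])


class TestEnsembleModels:
    def test_mean_ensemble_matches_brute_force(self, ensemble_repo):
        repo, sdf, members = (
            ensemble_repo["repo"], ensemble_repo["sdf"], ensemble_repo["members"],
        )
        if not repo.model_exists("ens-mean"):
            repo.new_model("ens-mean")
        pset = workflows.ParameterSet.load(repo.version_dir("ens-mean", "dev"))
        pset.update({"ensemble": {"members": members, "combination": "mean"}})
        pset.set("annotation.field", "activity")
        pset.save(repo.version_dir("ens-mean", "dev") / "parameters.yml")
        workflows.build(repo, "ens-mean", sdf)
        v = repo.publish("ens-mean")
        record = workflows.predict(repo, "ens-mean", v, sdf)
        dm, _ = ensemble_matrix(repo, [tuple(m) for m in members], sdf)
        brute = dm.X.mean(axis=1)
        values = [c["value"] for c in record.compounds if c["status"] == "ok"]
        assert np.allclose(values, brute, atol=1e-12)
        # per-member detail carries intervals from conformal members
        member0 = record.compounds[0]["members"][0]
        assert {"y_min", "y_max", "value"} <= set(member0)

    def test_conformal_outcomes_round_trip_through_report(self, qualitative_repo):
        repo, sdf, members = (
            qualitative_repo["repo"], qualitative_repo["sdf"], qualitative_repo["members"],
        )
        if not repo.model_exists("ens-vote"):
            repo.new_model("ens-vote")
        pset = workflows.ParameterSet.load(repo.version_dir("ens-vote", "dev"))
        pset.update({"ensemble": {"members": members, "combination": "majority"}})
        pset.set("annotation.field", "activity")
        pset.set("annotation.endpoint_type", "qualitative")
        pset.save(repo.version_dir("ens-vote", "dev") / "parameters.yml")
        workflows.build(repo, "ens-vote", sdf)
        v = repo.publish("ens-vote")
        record = workflows.predict(repo, "ens-vote", v, sdf)
        allowed = {"positive", "negative", "inconclusive_I", "inconclusive_II"}
        for compound in record.compounds:
            assert len(compound["members"]) == 3
            for detail in compound["members"]:
                assert detail["outcome"] in allowed
            # combined result equals brute-force majority of member values
            votes = [d["value"] for d in compound["members"]]
            expected = combine(votes, "majority", "qualitative")
            got = compound.get("value", compound.get("outcome"))
            assert got == expected

    def test_meta_ensemble_close_to_best_member(self, ensemble_repo):
        repo, sdf, members = (
            ensemble_repo["repo"], ensemble_repo["sdf"], ensemble_repo["members"],
        )
        if not repo.model_exists("ens-meta"):
            repo.new_model("ens-meta")
        pset = workflows.ParameterSet.load(repo.version_dir("ens-meta", "dev"))
        pset.update({
            "ensemble": {"members": members, "combination": "meta",
                         "meta": {"method": "PLS"}},
            "descriptors": {"scaling": "raw"},
        })
        pset.set("annotation.field", "activity")
        pset.save(repo.version_dir("ens-meta", "dev") / "parameters.yml")
        report = workflows.build(repo, "ens-meta", sdf)
        member_q2 = []
        for name, version in members:
            from modelkiln.metrics import QualityReport

            r = QualityReport.load(repo.version_dir(name, version) / QualityReport.FILENAME)
            member_q2.append(r.prediction["q2"])
        assert report.prediction["q2"] >= max(member_q2) - 0.05

    def test_single_member_rejected(self, ensemble_repo):
        repo, sdf = ensemble_repo["repo"], ensemble_repo["sdf"]
        if not repo.model_exists("ens-one"):
            repo.new_model("ens-one")
        pset = workflows.ParameterSet.load(repo.version_dir("ens-one", "dev"))
        pset.update({"ensemble": {"members": [["rf-member", 1]]}})
        pset.set("annotation.field", "activity")
        pset.save(repo.version_dir("ens-one", "dev") / "parameters.yml")
        with pytest.raises(ConfigurationError, match="at least 2"):
            workflows.build(repo, "ens-one", sdf)

    def test_deleted_member_breaks_prediction_with_traceability_error(
        self, tmp_path, ensemble_repo
    ):
        # isolated repo so the shared fixture members survive
        src, sdf = ensemble_repo["repo"], ensemble_repo["sdf"]
        repo = ModelRepository(tmp_path / "r")
        for name in ("rf-member", "pls-member"):
            repo.import_model(src.export_model(name, tmp_path / f"{name}.mkiln"))
        repo.new_model("ens")
        pset = workflows.ParameterSet.load(repo.version_dir("ens", "dev"))
        pset.update({"ensemble": {"members": [["rf-member", 1], ["pls-member", 1]],
                                  "combination": "mean"}})
        pset.set("annotation.field", "activity")
        pset.save(repo.version_dir("ens", "dev") / "parameters.yml")
        workflows.build(repo, "ens", sdf)
        v = repo.publish("ens")
        repo.remove("pls-member")
        with pytest.raises(FatalError, match="deleted since build"):
            workflows.predict(repo, "ens", v, sdf)
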