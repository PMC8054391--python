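import pytest

from modelkiln import workflows
from modelkiln.fixtures import FixtureSpec, generate_series
from modelkiln.repository import ModelRepository


@pytest.fixture(scope="session")
def series_paths(tmp_path_factory):
    """A 60-compound quantitative synthetic series (SDF + truth table)."""
    tmp = tmp_path_factory.mktemp("series")
    sdf, truth = tmp / "train.sdf", tmp / "train.truth.tsv"
    generate_series(FixtureSpec(n=60, seed=46, noise_sd=0.3), sdf, truth)
    return sdf, truth


@pytest.fixture(scope="session")
def built_repo(tmp_path_factory, series_paths):
    """A repository with one built and published quantitative model.

    Session-scoped and treated as read-only by tests; anything that
    rebuilds or mutates makes its own repository.
    """
    repo = ModelRepository(tmp_path_factory.mktemp("repo"))
    repo.new_model("acme")
    report = workflows.build(
        repo, "acme", series_paths[0], overrides=["annotation.field=activity"]
    )
    version = repo.publish("acme")
    return {
        "repo": repo,
        "name": "acme",
        "version": version,
        "sdf": series_paths[0],
        "report": report,
    }
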