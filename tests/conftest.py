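import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from xrefdb import fixtures, service, store  # noqa: E402


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory):
    """Built store + ground-truth graph for the worked-example universe."""
    root = tmp_path_factory.mktemp("worked_example")
    files, graph = fixtures.worked_example_fixture(str(root / "data"))
    handle = service.build(
        service.BuildConfig(registry_path=files["registry"], output_dir=str(root / "store"))
    )
    return handle, graph, files


@pytest.fixture(scope="session")
def universe(tmp_path_factory):
    """Built store + ground-truth graph for the seeded random universe."""
    root = tmp_path_factory.mktemp("universe")
    files, graph = fixtures.generate_universe(fixtures.UniverseParams(), str(root / "data"))
    handle = service.build(
        service.BuildConfig(registry_path=files["registry"], output_dir=str(root / "store"))
    )
    return handle, graph, files


@pytest.fixture()
def worked_example_store(worked_example):
    return worked_example[0]


@pytest.fixture()
def universe_store(universe):
    return universe[0]
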