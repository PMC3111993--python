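import pytest

from prokannot.core import PipelineThresholds
from prokannot.synthetic import FixtureSpec, make_evidence, make_toy_assembly


@pytest.fixture(scope="session")
def thresholds():
    return PipelineThresholds()


@pytest.fixture(scope="session")
def assembly():
    return make_toy_assembly(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def toy_evidence(assembly):
    return make_evidence(assembly)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The complete on-disk fixture file set (seed 1), written once."""
    from prokannot.synthetic import write_fixture

    out = tmp_path_factory.mktemp("fixture")
    write_fixture(out, FixtureSpec(seed=1))
    return out
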