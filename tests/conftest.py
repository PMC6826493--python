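import pytest

from mybsynnet import simulate as sim


@pytest.fixture(scope="session")
def null_dataset(tmp_path_factory):
    d = tmp_path_factory.mktemp("null")
    truth = sim.make_fixture("null", d)
    return d, truth


@pytest.fixture(scope="session")
def wgd_dataset(tmp_path_factory):
    d = tmp_path_factory.mktemp("wgd")
    truth = sim.make_fixture("wgd", d)
    return d, truth


@pytest.fixture(scope="session")
def tandem7_dataset(tmp_path_factory):
    d = tmp_path_factory.mktemp("tandem7")
    truth = sim.make_fixture("tandem7", d)
    return d, truth


@pytest.fixture(scope="session")
def two_clade_dataset(tmp_path_factory):
    d = tmp_path_factory.mktemp("two_clade")
    truth = sim.make_fixture("two_clade", d)
    return d, truth


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    d = tmp_path_factory.mktemp("default")
    truth = sim.make_fixture("default", d)
    return d, truth
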