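import pytest

from herbnet import core_io


@pytest.fixture(scope="session")
def compound_fixture():
    return core_io.load_compound_fixture()


@pytest.fixture(scope="session")
def target_fixture():
    return core_io.load_target_fixture()


@pytest.fixture(scope="session")
def common_gene_fixture():
    return core_io.load_common_gene_fixture()


@pytest.fixture(scope="session")
def rescue_ids():
    return core_io.load_rescue_ids()


@pytest.fixture(scope="session")
def organ_panel():
    return core_io.load_organ_panel()
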