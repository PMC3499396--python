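import pytest

from rmpmic import group_x_model, table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def xmodel():
    """The exact order-1 group-X simulation chain (length 5)."""
    return group_x_model(length=5)


@pytest.fixture(scope="session")
def table1_values(table1, xmodel):
    """Chain probabilities of the 17 worked-example sequences."""
    return [xmodel.sequence_probability(r.seq) for r in table1.records]
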