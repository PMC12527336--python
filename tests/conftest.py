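import pytest

from cocktailnet import worked_example_fixture


@pytest.fixture(scope="session")
def example():
    """The hand-checkable 8-phage x 5-host network with its interaction matrix."""
    return worked_example_fixture()


@pytest.fixture(scope="session")
def example_qpbin(example):
    return example[0]


@pytest.fixture(scope="session")
def example_qppin(example):
    return example[1]
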