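import pytest

from tendermcda import datasets


@pytest.fixture(scope="session")
def draft_framework():
    return datasets.indonesia_draft_framework()


@pytest.fixture(scope="session")
def final_framework():
    return datasets.indonesia_final_framework()


@pytest.fixture(scope="session")
def vote_rounds():
    return datasets.indonesia_votes()


@pytest.fixture(scope="session")
def test_cases():
    return datasets.indonesia_test_cases("final")
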