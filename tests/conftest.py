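import pytest

from wgdkit import teleost_species_tree
from wgdkit.classify import WgdClassifier


@pytest.fixture(scope="session")
def st():
    return teleost_species_tree()


@pytest.fixture()
def rigid(st):
    return WgdClassifier(st, "salmon", mode="rigid")


@pytest.fixture()
def relaxed(st):
    return WgdClassifier(st, "salmon", mode="relaxed")
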