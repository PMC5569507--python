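import numpy as np
import pytest

from srnakit.identify import CatalogEntry
from srnakit.preprocess import ReadSet


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture
def small_catalog():
    return [
        CatalogEntry("miR156", "UGACAGAAGAGAGUGAGCACA", "5p"),
        CatalogEntry("miR166", "UCGGACCAGGCUUCAUUCCCC", "3p"),
        CatalogEntry("miR390", "AAGCUCAGGAGGGAUAGCGCC", "5p"),
    ]


@pytest.fixture
def simple_readset():
    return ReadSet(counts={
        "UGACAGAAGAGAGUGAGCACA": 100,
        "UCGGACCAGGCUUCAUUCCCC": 50,
        "AAAACCCCGGGGUUUUAAAACCCC": 10,
    }, library_id="lib1")
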