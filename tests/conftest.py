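import numpy as np
import pytest

from markerlens.core_io import CountMatrix, parse_taxonomy
from markerlens.amplicon_diversity import ASVTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def small_table():
    """4 samples x 3 ASVs with one low-count sample and one low-count ASV."""
    counts = np.array(
        [
            [60, 50, 0],
            [70, 40, 1],
            [55, 45, 0],
            [50, 30, 0],  # sum 80 < 100 -> dropped by the count filter
        ]
    )
    matrix = CountMatrix(["s1", "s2", "s3", "s4"], ["a1", "a2", "a3"], counts)
    tax = {
        "a1": parse_taxonomy(
            "d__Bacteria;p__Bacillota_A;c__Clostridia;o__Oscillospirales;"
            "f__Oscillospiraceae;g__Vescimonas;s__"
        ),
        "a2": parse_taxonomy(
            "d__Bacteria;p__Bacillota_A;c__Clostridia;o__Oscillospirales;"
            "f__Oscillospiraceae;g__CAG-170;s__"
        ),
        "a3": parse_taxonomy(
            "d__Bacteria;p__Bacillota_A;c__Clostridia;o__Lachnospirales;"
            "f__Lachnospiraceae;g__CAG-81;s__"
        ),
    }
    return ASVTable(matrix, tax)
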