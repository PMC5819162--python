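import numpy as np
import pytest

from chromasig.genome import BinGrid, SubtypeDesign


@pytest.fixture
def grid():
    """Two small chromosomes, 200 bp bins (5 + 3 bins, last bin truncated)."""
    return BinGrid({"chr1": 1000, "chr2": 500}, 200)


@pytest.fixture
def cohort_grid():
    """A grid large enough for cohort-level experiments (4000 bins)."""
    return BinGrid({"chr1": 500_000, "chr2": 300_000}, 200)


@pytest.fixture
def design3():
    """Three subtypes x two lines: one normal-like, one luminal, one TNBC."""
    lines = {
        "N1": "Normal",
        "N2": "Normal",
        "L1": "Luminal",
        "L2": "Luminal",
        "T1": "Basal",
        "T2": "Basal",
    }
    return SubtypeDesign(
        lines=list(lines),
        subtype_of=lines,
        normal_subtypes=frozenset({"Normal"}),
        tnbc_subtypes=frozenset({"Basal"}),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
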