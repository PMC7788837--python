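import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mixindep import GenotypeTable

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: 10 individuals x 2 markers (one STR, one SNP) — the layout of the
#: documented tabular input format, used as the hand-checkable worked example.
TOY_CELLS = [
    [("12", "12"), ("A", "A")],
    [("13", "14"), ("T", "T")],
    [("13", "13"), ("A", "T")],
    [("14", "15"), ("A", "T")],
    [("15", "13"), ("T", "A")],
    [("13", "14"), ("A", "T")],
    [("14", "3"), ("A", "A")],
    [("12", "2"), ("T", "A")],
    [("14", "14"), ("T", "T")],
    [("15", "15"), ("A", "T")],
]


@pytest.fixture
def toy_panel() -> GenotypeTable:
    return GenotypeTable.from_cells(
        [str(i) for i in range(1, 11)],
        ["STR1", "SNP1"],
        TOY_CELLS,
        marker_types=["STR", "SNP"],
    )


@pytest.fixture
def random_table() -> GenotypeTable:
    """20 x 5 random panel with some missing cells, for recount oracles."""
    rng = np.random.default_rng(7)
    alleles = ["8", "9", "10", "11"]
    cells = []
    for i in range(20):
        row = []
        for j in range(5):
            if rng.random() < 0.1:
                row.append(None)
            else:
                row.append((str(rng.choice(alleles)), str(rng.choice(alleles))))
            # keep at least one observed genotype per marker
        cells.append(row)
    for j in range(5):
        if all(cells[i][j] is None for i in range(20)):
            cells[0][j] = ("8", "9")
    return GenotypeTable.from_cells(
        [f"s{i}" for i in range(20)], [f"m{j}" for j in range(5)], cells
    )
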