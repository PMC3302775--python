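import numpy as np
import pytest

from dartpop import (
    BiallelicGenotypeMatrix,
    DissimilarityMatrix,
    GroupAssignment,
    MarkerMap,
    QMatrix,
    SyntheticConfig,
    simulate_population,
)


@pytest.fixture
def toy_gm() -> BiallelicGenotypeMatrix:
    """4 accessions x 5 markers with a couple of missing calls."""
    calls = np.array(
        [
            [1, 0, 1, 1, 0],
            [1, 1, 0, 1, np.nan],
            [0, 0, 1, 0, 1],
            [np.nan, 1, 1, 0, 1],
        ],
        dtype=float,
    )
    return BiallelicGenotypeMatrix(
        ["a1", "a2", "a3", "a4"], ["m1", "m2", "m3", "m4", "m5"], calls
    )


@pytest.fixture
def toy_map() -> MarkerMap:
    return MarkerMap(
        ["m1", "m2", "m3", "m4", "m5"],
        ["chr1", "chr1", "chr1", "chr2", "chr2"],
        np.array([100, 5_100, 1_000_100, 200, 50_200]),
    )


@pytest.fixture(scope="session")
def small_panel():
    """Scaled-down structured panel shared across tests: 6 unequal groups,
    denser-than-default marker spacing so every distance class is populated."""
    cfg = SyntheticConfig(
        n_chromosomes=10,
        chromosome_length_bp=2_000_000,
        n_markers=400,
        seed=11,
    )
    return simulate_population(cfg)


def make_q(rows, ids=None) -> QMatrix:
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"a{i + 1}" for i in range(rows.shape[0])]
    return QMatrix(list(ids), rows)
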