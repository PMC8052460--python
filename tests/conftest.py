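import numpy as np
import pandas as pd
import pytest

from tetrasnp.io import ClonePanel, DosageMatrix, MarkerMap
from tetrasnp.simulate import SimConfig, simulate_structured_population


@pytest.fixture(scope="session")
def small_panel():
    """60-clone x 400-marker structured panel with truth, shared across tests."""
    cfg = SimConfig(n_per_pop=(20, 20, 20), m_markers=400, fst=(0.15, 0.15, 0.15), seed=11)
    return simulate_structured_population(cfg)


@pytest.fixture
def toy_matrix():
    """Tiny hand-checkable tetraploid matrix (3 clones x 4 markers)."""
    dosage = np.array(
        [
            [0.0, 1.0, 4.0, 2.0],
            [4.0, 2.0, 2.0, np.nan],
            [2.0, 0.0, 0.0, 3.0],
        ]
    )
    return DosageMatrix(["a", "b", "c"], ["m1", "m2", "m3", "m4"], dosage, ploidy=4)


@pytest.fixture
def toy_map():
    return MarkerMap(
        pd.DataFrame(
            {
                "marker_id": ["m1", "m2", "m3", "m4"],
                "chrom": [1, 1, 2, 2],
                "pos": [100, 1100, 500, 40_500],
            }
        )
    )


@pytest.fixture
def toy_clone_panel():
    return ClonePanel(
        pd.DataFrame(
            {
                "clone_id": ["a", "b", "c"],
                "market_class": ["Red", "Russet", "Chipping"],
                "code": ["R", "Ru", "W"],
            }
        )
    )
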