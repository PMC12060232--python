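import numpy as np
import pytest

from rilqtl.core import AncestryMatrix
from rilqtl.simulate import PanelConfig, simulate_panel
from rilqtl.windows import flag_skewed


@pytest.fixture(scope="session")
def big_panel():
    """Default-size panel: 278 RILs, ~1,030 windows over 5 arms."""
    return simulate_panel(PanelConfig(seed=1))


@pytest.fixture(scope="session")
def big_summary(big_panel):
    matrix, _ = big_panel
    return flag_skewed(matrix)


@pytest.fixture(scope="session")
def small_panel():
    """Small panel for fast tests: 60 RILs, 150 windows over 3 arms."""
    cfg = PanelConfig(
        n_rils=60,
        arms=[("chrA", 50, 50.0), ("chrB", 50, 50.0), ("chrC", 50, 50.0)],
        seed=7,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_summary(small_panel):
    matrix, _ = small_panel
    return flag_skewed(matrix)


@pytest.fixture()
def tiny_matrix():
    """Hand-sized matrix: 8 RILs x 4 windows with all genotype combos."""
    dosage = np.array(
        [
            [0, 0, 0, 2],
            [0, 2, 1, 2],
            [2, 0, 2, 0],
            [2, 2, 0, 0],
            [1, 1, 2, 2],
            [0, 1, 1, 0],
            [2, 1, 0, 2],
            [1, 2, 2, 0],
        ],
        dtype=float,
    )
    rils = np.array([f"r{i}" for i in range(8)], dtype=object)
    wins = np.array(["w1", "w2", "w3", "w4"], dtype=object)
    return AncestryMatrix(rils, wins, dosage)
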