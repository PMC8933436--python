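import numpy as np
import pytest

import diplomap as dm
from diplomap.panels import MAT_A, MAT_ALPHA


@pytest.fixture(scope="session")
def small_map():
    return dm.yeast_like_map(n_markers=120, n_chrom=16, total_cm=750.0)


@pytest.fixture(scope="session")
def small_panel(small_map):
    """60 MATa x 65 MATalpha factorial panel (3,900 diploids)."""
    hap = dm.simulate_gametes(small_map, 130, seed=11)
    mata = hap.subset(hap.mating_type == MAT_A)
    matalpha = hap.subset(hap.mating_type == MAT_ALPHA)
    return dm.mate_panels(mata.subset(np.arange(60)), matalpha.subset(np.arange(65)))


@pytest.fixture(scope="session")
def tiny_panel(small_map):
    """10 x 12 parents: 120 diploids, cheap enough for pooled-count simulation."""
    hap = dm.simulate_gametes(small_map, 50, seed=1)
    mata = hap.subset(hap.mating_type == MAT_A)
    matalpha = hap.subset(hap.mating_type == MAT_ALPHA)
    return dm.mate_panels(mata.subset(np.arange(10)), matalpha.subset(np.arange(12)))
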