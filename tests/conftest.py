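import numpy as np
import pandas as pd
import pytest

from feralscan.io import HaplotypeMatrix, PopulationMap
from feralscan.pipeline import demo_config
from feralscan.simulate import simulate_populations


@pytest.fixture(scope="session")
def demo_sim():
    """One small end-to-end study: planted regions, a sweep, mosaics."""
    return simulate_populations(demo_config(1).simulation)


@pytest.fixture
def tiny_matrix():
    """2 samples x 4 sites with one missing genotype."""
    alleles = np.array([
        [0, 1, 0, 1],
        [1, 1, 0, 0],
        [0, 0, 1, 1],
        [-1, 0, 1, 1],
    ], dtype=np.int8)
    sites = pd.DataFrame({
        "chrom": ["chr1"] * 4,
        "pos": [100, 200, 300, 400],
        "ref": ["A", "C", "G", "T"],
        "alt": ["T", "G", "A", "C"],
    })
    return HaplotypeMatrix(alleles, sites, ["s1", "s2"])


@pytest.fixture
def tiny_popmap():
    return PopulationMap({"s1": "weed", "s2": "crop"})
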