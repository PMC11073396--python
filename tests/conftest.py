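import numpy as np
import pandas as pd
import pytest

from assemblage.io_core import AbundanceTable, SampleMetadata, read_tree
from assemblage.synthetic import DesignConfig, RegimeConfig, generate_study

NEWICK_3 = "((A:1,B:1):1,C:2);"


@pytest.fixture
def tree3():
    """Three-tip tree with hand-checkable path lengths."""
    return read_tree(NEWICK_3)


@pytest.fixture
def small_table():
    counts = np.array([
        [5, 0, 3],
        [1, 2, 0],
        [0, 7, 4],
    ])
    return AbundanceTable(["A", "B", "C"], ["s1", "s2", "s3"], counts)


@pytest.fixture
def small_metadata():
    return SampleMetadata(pd.DataFrame(dict(
        sample_id=["s1", "s2", "s3"],
        lake=["L1", "L1", "L1"],
        day=[3, 3, 7],
        polymer=["PP", "PE", "PP"],
        fraction=["plastisphere"] * 3,
    )))


@pytest.fixture(scope="session")
def tiny_study():
    """One-lake study small enough for per-test analysis."""
    design = DesignConfig(n_lakes=1, polymers=("PP", "PE", "PVC", "PS"),
                          days=(3, 15, 60), n_taxa=80, sequencing_depth=500,
                          seed=42)
    regime = RegimeConfig()
    return generate_study(design, regime)
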