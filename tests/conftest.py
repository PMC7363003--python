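import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from ecoassembly import CommunityTable, EnvironmentDesign

THREE_TIP_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def three_tip_tree() -> TreeNode:
    return TreeNode.read(io.StringIO(THREE_TIP_NEWICK))


@pytest.fixture
def toy_table() -> CommunityTable:
    # OTU1 in envs {A,B}, OTU2 in {A}, OTU3 in {A,B,C}
    counts = pd.DataFrame(
        {"sa1": [5, 2, 1], "sa2": [0, 3, 4],
         "sb1": [7, 0, 2], "sc1": [0, 0, 9]},
        index=["OTU1", "OTU2", "OTU3"])
    return CommunityTable(counts)


@pytest.fixture
def toy_design() -> EnvironmentDesign:
    frame = pd.DataFrame(
        {"environment": ["A", "A", "B", "C"],
         "ph": [5.0, 5.5, 6.5, 7.0]},
        index=pd.Index(["sa1", "sa2", "sb1", "sc1"], name="sample_id"))
    return EnvironmentDesign(frame)


def random_table(rng: np.random.Generator, n_otus: int, n_samples: int,
                 max_count: int = 20) -> CommunityTable:
    counts = rng.integers(0, max_count + 1, size=(n_otus, n_samples))
    # keep every sample non-empty
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[rng.integers(n_otus), j] = 1
    return CommunityTable(pd.DataFrame(
        counts, index=[f"O{i}" for i in range(n_otus)],
        columns=[f"s{j}" for j in range(n_samples)]))
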