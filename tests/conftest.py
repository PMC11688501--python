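import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from reservoirlink.core_data import CountTable, SampleMetadata, TaxonomyTable


@pytest.fixture
def toy_table() -> CountTable:
    """3 samples x 3 taxa with known totals (A:49, B:50, C:3)."""
    return CountTable(pd.DataFrame(
        [[10, 20, 1], [19, 10, 1], [20, 20, 1]],
        index=["s1", "s2", "s3"], columns=["A", "B", "C"],
    ))


@pytest.fixture
def toy_tree() -> TreeNode:
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def pair_table() -> CountTable:
    """The two hand-worked samples x=(2,1,0), y=(1,1,1)."""
    return CountTable(pd.DataFrame(
        [[2, 1, 0], [1, 1, 1]], index=["x", "y"], columns=["A", "B", "C"],
    ))


@pytest.fixture
def toy_taxonomy() -> TaxonomyTable:
    return TaxonomyTable(pd.DataFrame({
        "taxon_id": ["A", "B", "C"],
        "family": ["Fam1", "Fam1", "Fam2"],
        "genus": ["G1", "G1", ""],
    }))


@pytest.fixture
def exchange_meta_small() -> SampleMetadata:
    rows = []
    for w, trt, tag in [(0, "none", "start"), (1, "native", "N"), (1, "foreign", "F")]:
        for j in range(3):
            rows.append((f"{tag}{j}", "polyp", "pop0", "pop0", w, trt, f"{tag}{j}"))
    return SampleMetadata(pd.DataFrame(
        rows, columns=["sample_id", "sample_type", "population", "site",
                       "timepoint", "treatment", "jar"],
    ))
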