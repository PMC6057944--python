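import numpy as np
import pandas as pd
import pytest

from gradientscope.core_data import FeatureTable, SampleMetadata, TaxonomyMap


@pytest.fixture
def tiny_table() -> FeatureTable:
    data = pd.DataFrame(
        [[3, 0, 4], [4, 2, 0], [0, 5, 1]],
        index=["OTU1", "OTU2", "OTU3"],
        columns=["S1", "S2", "S3"],
    )
    return FeatureTable(data)


@pytest.fixture
def tiny_taxonomy() -> TaxonomyMap:
    return TaxonomyMap.from_lineages(
        {
            "OTU1": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; "
                    "f__Ruminococcaceae; g__Oscillospira; s__",
            "OTU2": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; "
                    "f__Prevotellaceae; g__Prevotella; s__",
            "OTU3": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; "
                    "f__Ruminococcaceae; g__; s__",
        }
    )


@pytest.fixture
def four_group_metadata() -> SampleMetadata:
    rows = []
    codes = {"captive": "c", "semi-captive": "sc", "semi-wild": "sw", "wild": "w"}
    for g, n in [("captive", 4), ("semi-captive", 4), ("semi-wild", 4), ("wild", 4)]:
        for i in range(n):
            rows.append((f"{codes[g]}{i}", f"ind_{g}_{i}", g))
    df = pd.DataFrame(rows, columns=["sample_id", "individual_id", "lifestyle"])
    return SampleMetadata(df.set_index("sample_id"))


@pytest.fixture
def random_table() -> FeatureTable:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(200, 10))
    counts[:, counts.sum(axis=0) == 0] += 1
    return FeatureTable(
        pd.DataFrame(
            counts,
            index=[f"F{i:03d}" for i in range(200)],
            columns=[f"S{j}" for j in range(10)],
        )
    )
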