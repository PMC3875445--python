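import numpy as np
import pandas as pd
import pytest

from mirshift.quantify import CountMatrix


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """Four features x four libraries with easy hand arithmetic."""
    counts = pd.DataFrame(
        {
            "L1": [5000, 0, 120, 10],
            "L2": [5000, 80, 960, 0],
            "L3": [2500, 40, 60, 5],
            "L4": [2500, 40, 15, 5],
        },
        index=pd.Index(["miR-a", "miR-b", "miR-c", "miR-d"], name="feature_id"),
    )
    lengths = pd.Series([22, 20, 25, 22], index=counts.index)
    totals = pd.Series({"L1": 10_000_000, "L2": 10_000_000, "L3": 5_000_000, "L4": 5_000_000})
    return CountMatrix(counts, lengths, totals)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130812)
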