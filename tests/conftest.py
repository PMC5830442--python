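import numpy as np
import pandas as pd
import pytest

from metaneighbor.io import ExpressionStudy, merge_on_gene_universe
from metaneighbor.synthetic import SyntheticConfig, generate


@pytest.fixture
def two_tiny_studies():
    """Two hand-written 4-gene studies with overlapping gene lists."""
    s1 = ExpressionStudy(
        "s1",
        pd.DataFrame(
            [[1.0, 2.0], [3.0, 0.0], [0.0, 5.0], [2.0, 2.0]],
            index=["gA", "gB", "gC", "gD"],
            columns=["c1", "c2"],
        ),
    )
    s2 = ExpressionStudy(
        "s2",
        pd.DataFrame(
            [[4.0, 1.0, 0.0], [2.0, 2.0, 7.0], [1.0, 0.0, 3.0]],
            index=["gB", "gC", "gE"],
            columns=["c1", "c2", "c3"],
        ),
    )
    return [s1, s2]


@pytest.fixture
def tiny_metadata():
    return pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c1", "c2", "c3"],
            "study_id": ["s1", "s1", "s2", "s2", "s2"],
            "cell_type": ["alpha", "beta", "alpha", "beta", "alpha"],
        }
    )


@pytest.fixture(scope="session")
def strong_signal():
    """Three studies, two well-separated planted types, with batch effects."""
    config = SyntheticConfig(seed=7, effect_size=3.0)
    studies, metadata, markers = generate(config)
    merged = merge_on_gene_universe(studies, metadata=metadata)
    return studies, metadata, markers, merged
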