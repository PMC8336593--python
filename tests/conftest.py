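import numpy as np
import pandas as pd
import pytest

from ltrdose.diagnostics import random_extended  # noqa: F401  (shared helper)
from ltrdose.features import MONO


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_records():
    """Two drugs, one cell line: the full 4x4 grid plus monotherapies."""
    rows = []
    for ca in range(1, 5):
        for cb in range(1, 5):
            rows.append(("A", "B", ca, cb, "c1", 10.0 * ca - cb))
    for d in ("A", "B"):
        for ca in range(1, 5):
            rows.append((d, MONO, ca, 0, "c1", 5.0 * ca))
    return pd.DataFrame(
        rows, columns=["drug_a", "drug_b", "conc_a", "conc_b",
                       "cell_line", "response"])
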