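import numpy as np
import pandas as pd
import pytest

import itemscreen as its


@pytest.fixture(scope="session")
def phase3():
    """The packaged published per-item table, loaded once."""
    stats, flags, decisions = its.load_phase3_item_table()
    return {"stats": stats, "flags": flags, "decisions": decisions,
            "by_id": {s.item_id: (s, f, d)
                      for s, f, d in zip(stats, flags, decisions)}}


@pytest.fixture
def four_items():
    return its.build_items([
        its.ItemMetadata("q1"),
        its.ItemMetadata("q2"),
        its.ItemMetadata("q3", reverse_coded=True),
        its.ItemMetadata("q4"),
    ])


def make_matrix(cells, items=None, patient_prefix="p"):
    """Build a ResponseMatrix from a dict of item -> list of values
    (None = missing), with default 1-4 metadata."""
    df = pd.DataFrame({k: [np.nan if v is None else float(v) for v in vals]
                       for k, vals in cells.items()})
    n = len(df)
    df.index = [f"{patient_prefix}{i + 1}" for i in range(n)]
    if items is None:
        items = its.build_items([its.ItemMetadata(k) for k in cells])
    return its.ResponseMatrix(df, items)


@pytest.fixture
def matrix_factory():
    return make_matrix
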