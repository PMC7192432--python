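import numpy as np
import pandas as pd
import pytest

import dfakit as dk


@pytest.fixture(scope="session")
def small_panel():
    """A small fully-known simulated anomaly panel with ground truth."""
    rng = np.random.default_rng(42)
    X = dk.simulate_trends(2, 60, rng=rng)
    Z = dk.build_block_loadings(4, ("a", "b"), "by-geography", magnitude=0.6)
    R = 0.3 * np.eye(8)
    Y = dk.simulate_observations(X, Z, R, rng=rng)
    meta = pd.DataFrame(
        {
            "station": [f"S{i // 2 + 1:02d}" for i in range(8)],
            "class": ["a", "b"] * 4,
        },
        index=[f"S{i // 2 + 1:02d}_{'ab'[i % 2]}" for i in range(8)],
    )
    return {"Y": Y, "X": X, "Z": Z, "R": R, "meta": meta}


@pytest.fixture(scope="session")
def sample_table():
    """Long-format sample table covering replicates, months and classes."""
    rows = [
        # two same-day replicates (2, 4) and one later date (6) -> mean 4.5
        ("S01", "2001-07-10", "diatoms", 2.0),
        ("S01", "2001-07-10", "diatoms", 4.0),
        ("S01", "2001-08-02", "diatoms", 6.0),
        # June sample must be excluded
        ("S01", "2001-06-20", "diatoms", 100.0),
        ("S01", "2002-07-15", "diatoms", 8.0),
        ("S02", "2001-07-04", "diatoms", 1.0),
        ("S02", "2002-08-20", "diatoms", 3.0),
        ("S01", "2001-07-10", "cryptophytes", 1.0),
        ("S01", "2002-07-15", "cryptophytes", 0.0),
        ("S02", "2001-07-04", "cryptophytes", 2.0),
        ("S02", "2002-08-20", "cryptophytes", 4.0),
    ]
    df = pd.DataFrame(rows, columns=["station", "date", "class", "value"])
    df["unit"] = "mg m-3"
    return df
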