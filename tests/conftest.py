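import numpy as np
import pandas as pd
import pytest

import mifpipe as m


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Small degenerate cohort: every MFI equals its on/off location."""
    cfg = m.zero_noise_config(cells_per_sample=300)
    tables, regions, truth = m.generate_cohort(cfg)
    return cfg, tables, regions, truth


@pytest.fixture
def two_clouds():
    """Two point clouds separated by ~100x their internal spread."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 1.0, size=(30, 6))
    b = rng.normal(200.0, 1.0, size=(30, 6))
    X = np.vstack([a, b])
    labels = np.array([0] * 30 + [1] * 30)
    return X, labels


@pytest.fixture
def small_cell_table():
    df = pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3"],
            "x": [1.0, 2.0, 3.0],
            "y": [4.0, 5.0, 6.0],
            "nuclear_size": [30.0, 40.0, 50.0],
            "CD31": [0.1, 0.2, 0.3],
            "SOX10": [5.0, 6.0, 7.0],
        }
    )
    return m.CellTable(sample_id="s1", df=df)
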