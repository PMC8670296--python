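import numpy as np
import pandas as pd
import pytest

import methpanel as mp


@pytest.fixture(scope="session")
def reference():
    return mp.load_reference_markers()


@pytest.fixture(scope="session")
def reference_summaries(reference):
    return [mp.marker_summary_from_reference(r) for r in reference.values()]


def make_matrix(values, genes, classes, ages=None, msi=None, sample_ids=None):
    """Build a MethylationMatrix from plain lists (test helper)."""
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(values.shape[0])]
    return mp.MethylationMatrix(
        pd.DataFrame(values, index=sample_ids, columns=genes),
        pd.Series(classes, index=sample_ids),
        None if ages is None else pd.Series(ages, index=sample_ids, dtype=float),
        None if msi is None else pd.Series(msi, index=sample_ids),
    )


@pytest.fixture
def toy_matrix():
    """5 samples x 4 genes with both classes, fixed values."""
    rng = np.random.default_rng(42)
    return make_matrix(
        rng.uniform(0, 100, size=(5, 4)),
        ["g1", "g2", "g3", "g4"],
        [mp.CARCINOMA] * 3 + [mp.NORMAL] * 2,
    )
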