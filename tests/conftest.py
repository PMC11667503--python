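import numpy as np
import pandas as pd
import pytest

import tmtpipe as tp


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_dataset(values, sample_ids=None, feature_ids=None, scale="log2", **trait_cols):
    """Small Dataset builder for hand fixtures."""
    values = np.asarray(values, dtype=float)
    n_f, n_s = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n_s)]
    feature_ids = feature_ids or [f"P{i}" for i in range(n_f)]
    mat = tp.AbundanceMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids), scale)
    traits = {"sample_id": sample_ids, "batch": trait_cols.pop("batch", ["b0"] * n_s)}
    traits.update(trait_cols)
    tt = tp.TraitTable(pd.DataFrame(traits).set_index("sample_id"))
    return tp.Dataset(mat, tt)


@pytest.fixture
def tiny_cohort():
    """Small seeded synthetic cohort shared by fast tests."""
    cfg = tp.SimConfig(n_proteins=150, n_samples=120, n_batches=8, seed=7)
    return tp.simulate_cohort(cfg)
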