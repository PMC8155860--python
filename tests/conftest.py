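import numpy as np
import pandas as pd
import pytest

import mirpair as mp


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down simulated dataset: same design, fewer features."""
    return mp.generate_dataset(mp.scaled_config(seed=1))


@pytest.fixture(scope="session")
def default_sim():
    """Full study-design simulation: 3v4 samples, 75 DE miRNAs, 562 DE mRNAs."""
    return mp.generate_dataset(mp.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_pair_chain(small_sim):
    """DE selection + full pair-inference chain on the scaled dataset."""
    dataset, truth, dbs, _ = small_sim
    de_mi = mp.differential_expression(dataset.mirna, dataset.groups)
    de_mr = mp.differential_expression(dataset.mrna, dataset.groups)
    sel_mi = mp.select_significant(de_mi)
    sel_mr = mp.select_significant(de_mr)
    pair_set = mp.infer_pairs(
        dataset.mirna.loc[sel_mi["feature_id"]],
        dataset.mrna.loc[sel_mr["feature_id"]],
        sel_mi, sel_mr, dbs, condition_label="small",
    )
    return dataset, truth, dbs, de_mi, de_mr, pair_set


def toy_pair_set(pairs, label="toy", **extra_columns):
    """A PairSet from explicit (mirna, mrna) tuples, for combinatorial tests."""
    df = pd.DataFrame(pairs, columns=["mirna_id", "mrna_id"])
    for col, values in extra_columns.items():
        df[col] = values
    return mp.PairSet(df, {"n_predicted_intersection": len(df)}, label)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
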