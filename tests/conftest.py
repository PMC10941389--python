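import numpy as np
import pandas as pd
import pytest

from resilink import microbiome, synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_cohort():
    """192-animal cohort with feed and microbiome data, shared across tests."""
    cfg = synthdata.SimulationConfig(
        n_animals=192, n_asv=300, n_informative_asv=30, target_m2=0.25
    )
    meta = synthdata.simulate_cohort(cfg, seed=101)
    visits, feed_truth = synthdata.simulate_feed_intake(cfg, meta, seed=102)
    counts, planted, micro_truth = synthdata.simulate_microbiome(cfg, meta, seed=103)
    return {
        "config": cfg,
        "meta": meta,
        "visits": visits,
        "feed_truth": feed_truth,
        "counts": counts,
        "planted": planted,
        "micro_truth": micro_truth,
    }


@pytest.fixture(scope="session")
def toy_counts():
    return pd.DataFrame(
        [[10, 5, 0, 1], [3, 3, 3, 3], [0, 0, 50, 2], [8, 0, 0, 0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["a1", "a2", "a3", "a4"],
    )


@pytest.fixture(scope="session")
def toy_clr(toy_counts):
    return microbiome.clr_transform(toy_counts)
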