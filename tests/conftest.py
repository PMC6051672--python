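import numpy as np
import pandas as pd
import pytest

import tnfit
from tnfit.io import SITE_INDEX, SampleCounts


def make_counts(mapping, **kwargs):
    """SampleCounts from {(replicon, pos, strand): reads}."""
    idx = pd.MultiIndex.from_tuples(list(mapping), names=SITE_INDEX)
    defaults = dict(sample_id="s", condition="both", growth_period=0, replicate=1)
    defaults.update(kwargs)
    return SampleCounts(counts=pd.Series(list(mapping.values()), index=idx), **defaults)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated screen shared across tests."""
    cfg = tnfit.SimConfig(
        seed=11,
        n_genes=120,
        n_insertions=8000,
        read_depth=400_000,
        n_sensitive_genes=5,
    )
    return tnfit.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_fit(small_sim):
    model = tnfit.TnseqScreen.from_simulation(small_sim)
    return model, model.fit()
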