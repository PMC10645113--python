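import numpy as np
import pandas as pd
import pytest

import hyenatrack as ht
from hyenatrack import classify as cl


@pytest.fixture(scope="session")
def training_table():
    """Well-separated 5-state benchmark table: 4 individuals x 3 audits
    x 10 min at 25 Hz."""
    audits, traces = ht.make_training_fixture(seed=17)
    return cl.build_training_table(audits, traces)


@pytest.fixture(scope="session")
def biased_training_table():
    """Same benchmark with a 0.2 g per-audit offset injected, emulating
    bout-specific collar shift."""
    audits, traces = ht.make_training_fixture(seed=17, audit_bias_sd=0.2)
    return cl.build_training_table(audits, traces)


@pytest.fixture(scope="session")
def small_population():
    """5 individuals x 4 days of true behaviour sequences (defaults)."""
    cfg = ht.PopulationConfig(n_individuals=5, n_days=4, seed=11)
    return cfg, ht.generate_state_sequences(cfg)


def constant_trace(value, n=100, rate=25.0, **kw):
    samples = np.tile(np.asarray(value, dtype=float), (n, 1))
    return ht.AccelTrace(pd.Timestamp("2017-01-01"), rate, samples, **kw)
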