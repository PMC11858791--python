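import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mongoose_arts import SimConfig, derive_all, generate_population
from mongoose_arts.mcmc import McmcConfig

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic population shared across read-only tests."""
    return generate_population(SimConfig(n_groups=4, n_events_per_group=8, seed=1))


@pytest.fixture(scope="session")
def small_derived(small_dataset):
    return derive_all(small_dataset.tables())


@pytest.fixture
def fast_config():
    """Short chains for sampler-behaviour tests (not convergence tests)."""
    return McmcConfig(chains=3, iterations=900, burnin=300, thin=1, seed=42)


@pytest.fixture
def weights_frame():
    def make(days_grams, base=pd.Timestamp("2015-06-01")):
        return pd.DataFrame(
            {
                "date": [base + pd.Timedelta(days=int(d)) for d, _ in days_grams],
                "grams": [g for _, g in days_grams],
            }
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(7)
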