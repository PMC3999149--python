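import numpy as np
import pytest

from mvgwas.simulate import ScenarioSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def qtl_dataset():
    """One replicate with a strong QTL on trait 1 (h2 = 2%) for signal tests."""
    spec = ScenarioSpec(
        maf_q=0.4, h2=(0.02, 0.0, 0.0), effect_sign=(1, 0, 0),
        residual_corr=0.3, n_individuals=1000, seed=101,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def null_dataset():
    """One replicate with no QTL effect on any trait."""
    spec = ScenarioSpec(
        maf_q=0.4, h2=(0.0, 0.0, 0.0), effect_sign=(0, 0, 0),
        residual_corr=0.3, n_individuals=1000, seed=102,
    )
    return simulate_dataset(spec)
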