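import numpy as np
import pytest

from choqgcn.pipeline import PipelineConfig
from choqgcn.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """200-sample strong-signal cohort shared across pipeline tests."""
    spec = CohortSpec(
        n_samples=200, n_ge=60, n_cna=40, n_cln=10, effect_size=3.0, seed=11
    )
    ge, cna, cln, labels, truth = generate_cohort(spec)
    return {"GE": ge, "CNA": cna, "CLN": cln}, labels, truth


@pytest.fixture
def fast_config():
    """Reduced-size pipeline configuration so tests stay inside the budget."""
    return PipelineConfig(
        n_folds=4,
        seed=7,
        mrmr_n_ge=20,
        mrmr_n_cna=10,
        hidden_sizes=(16, 8),
        epochs=40,
        learning_rate=0.01,
    )
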