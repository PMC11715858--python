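import numpy as np
import pytest

from truthbench import ScenarioSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uni_spec_small():
    """Small continuous univariate scenario for fast unit tests."""
    return ScenarioSpec(
        scenario_id="test-uni-c", arity="univariate",
        predictor_kinds=("continuous",), beta0=-0.5,
        betas=(float(np.log(2)),), n_total=600, n_reps=5, seed=42,
    )


@pytest.fixture
def bin_spec_small():
    return ScenarioSpec(
        scenario_id="test-uni-b", arity="univariate",
        predictor_kinds=("binary",), beta0=-0.5,
        betas=(float(np.log(3)),), binary_prevalence=0.3,
        n_total=600, n_reps=5, seed=43,
    )


@pytest.fixture
def multi_spec_small():
    return ScenarioSpec(
        scenario_id="test-multi", arity="multivariate",
        predictor_kinds=("continuous", "binary"), beta0=-0.8,
        betas=(float(np.log(2)), float(np.log(3))),
        binary_prevalence=0.3, causal_corr=0.3, proxy_corrs=(0.5,),
        n_total=600, n_reps=5, seed=44,
    )
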