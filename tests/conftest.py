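import numpy as np
import pytest

import rwmtune as rt


@pytest.fixture(scope="session")
def ar1_metric_d9():
    return rt.AR1Spec(rho=0.5, d=9).metric()


@pytest.fixture(scope="session")
def small_logistic_data():
    spec = rt.LogisticGenSpec(n=600, d=4, covariate_rho=0.5, seed=42)
    return rt.generate_logistic(spec)


def make_chain(states, accepted, initial_state, scaling=None, seed=0):
    """Assemble a ChainResult by hand for diagnostics unit tests."""
    if scaling is None:
        d = states.shape[1]
        scaling = rt.build_scaling(1.0, d)
    return rt.ChainResult(
        states=np.asarray(states, float),
        accepted=np.asarray(accepted, bool),
        seed=seed,
        scaling=scaling,
        initial_state=np.asarray(initial_state, float),
    )
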