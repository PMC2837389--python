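import numpy as np
import pytest

import smolsim as sm


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def run_config(text, seed=1, stop=None):
    model = sm.parse_config(text)
    if stop is not None:
        model.t_stop = stop
    sim = sm.init_sim(model, seed=seed)
    sim.run()
    return sim


@pytest.fixture
def run():
    return run_config
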