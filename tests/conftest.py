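import pytest

import spongenet as sp
from spongenet import diffexpr as dx


@pytest.fixture(scope="session")
def default_params():
    return sp.SimulationParams(seed=1)


@pytest.fixture(scope="session")
def default_bundle(default_params):
    """Simulated study at the default (stochastic-recovery) conditions."""
    truth = sp.generate_truth(default_params)
    design = sp.make_design(default_params.n_per_group)
    lnc, mir, mrna = sp.simulate_expression(truth, design, default_params)
    return default_params, truth, design, lnc, mir, mrna


@pytest.fixture(scope="session")
def default_de_tables(default_bundle):
    _, _, design, lnc, mir, mrna = default_bundle
    return tuple(dx.de_table(m, design) for m in (lnc, mir, mrna))


@pytest.fixture(scope="session")
def zero_noise_bundle():
    """Deterministic-verification conditions: no measurement noise, the
    planted triplets are the only DE transcripts."""
    params = sp.SimulationParams(
        noise_sd=0.0, signal_sd=0.5, de_fraction=0.0,
        n_triplets=5, n_decoys=60, seed=7,
    )
    truth = sp.generate_truth(params)
    design = sp.make_design(params.n_per_group)
    lnc, mir, mrna = sp.simulate_expression(truth, design, params)
    return params, truth, design, lnc, mir, mrna
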