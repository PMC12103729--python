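"""Shared fixtures: default plant, desk-scale datasets, and trained models.

Session-scoped so the expensive pieces (the 150-cycle protocol dataset and
the custom-dictionary fits) are built once for the whole run.
"""

import numpy as np
import pytest

from koopgait import (
    AnklePlantParams,
    DataGenConfig,
    generate_dataset,
    make_dictionary,
    make_reference,
    split_dataset,
)
from koopgait.edmd import fit_koopman
from koopgait.mpc import MPCProblem


@pytest.fixture(scope="session")
def params():
    return AnklePlantParams()


@pytest.fixture(scope="session")
def sine_ref(params):
    return make_reference("sinusoid", params, n_cycles=1, sample_rate=200.0)


@pytest.fixture(scope="session")
def dataset30(params):
    """30 ramp-protocol cycles: the scaled identification dataset."""
    return generate_dataset(DataGenConfig(n_cycles=30, seed=7), params)


@pytest.fixture(scope="session")
def dataset150(params):
    """The full printed protocol: 150 cycles x 200 samples at 200 Hz."""
    return generate_dataset(DataGenConfig(seed=0), params)


@pytest.fixture(scope="session")
def custom_model(dataset30, sine_ref):
    """Custom 13-observable model fitted on the 30-cycle training split."""
    train, _ = split_dataset(dataset30)
    return fit_koopman(train, sine_ref, make_dictionary("custom", 1), ridge=1e-8)


@pytest.fixture(scope="session")
def control_model(params, sine_ref):
    """Model for closed-loop control, trained with random input excitation."""
    cfg = DataGenConfig(n_cycles=30, seed=11, input_mode="random")
    train, _ = split_dataset(generate_dataset(cfg, params))
    return fit_koopman(train, sine_ref, make_dictionary("custom", 1), ridge=1e-8)


@pytest.fixture(scope="session")
def mpc_prob():
    return MPCProblem()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
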