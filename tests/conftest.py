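import numpy as np
import pytest

import occupet as op


@pytest.fixture(scope="session")
def schedule():
    return op.default_frame_schedule()


@pytest.fixture(scope="session")
def input_params():
    return op.InputFunctionParams()


@pytest.fixture(scope="session")
def truth():
    return op.default_ground_truth()


@pytest.fixture(scope="session")
def control_params(truth):
    """Baseline kinetics matching the control macro-parameters (V_T 0.87, BP 1.85)."""
    return truth.baseline


@pytest.fixture(scope="session")
def noiseless_control_tac(control_params, input_params, schedule):
    """Noiseless 2TRCM control TAC with Vb = 0.07 (whole blood mixed in)."""
    return op.simulate_tac(control_params, input_params, schedule, noise=None)


@pytest.fixture(scope="session")
def parent_model():
    return op.fit_parent_fraction(op.default_parent_samples())


@pytest.fixture(scope="session")
def corrected_blood(input_params, parent_model):
    """Sampled arterial series with parent-corrected plasma filled in."""
    raw = op.generate_input(input_params, op.default_blood_times(), parent_model)
    return op.correct_plasma(raw, parent_model)


@pytest.fixture(scope="session")
def analytic_grid(input_params, schedule):
    return op.analytic_input_grid(input_params, schedule)
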