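import numpy as np
import pytest

from fdopakin import input_function, synthetic, tac


@pytest.fixture(scope="session")
def if_schedule():
    return tac.make_schedule(tac.PROTOCOL_INPUT_FUNCTION)


@pytest.fixture(scope="session")
def uniform_schedule():
    return tac.make_schedule(tac.PROTOCOL_UNIFORM)


@pytest.fixture(scope="session")
def blood_model():
    """Exact continuous blood curve of the default generator scenario."""
    return synthetic.blood_model_from_spec(synthetic.BloodCurveSpec())


@pytest.fixture(scope="session")
def plasma(blood_model):
    """Plasma input model with default corrections (spill-out 0.51, hct 0.40)."""
    return input_function.build_plasma_input(blood_model, input_function.InputFunctionConfig())


@pytest.fixture(scope="session")
def labels_23_14():
    """23 wild-type (0) / 14 mutant (1) label vector."""
    return np.r_[np.zeros(23), np.ones(14)]
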