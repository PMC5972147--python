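import numpy as np
import pytest

from snailrelay import build_model
from snailrelay.calibrate import calibrated_params, design_center
from snailrelay.simulate import basal_state


@pytest.fixture(scope="session")
def full_model():
    return build_model("FULL")


@pytest.fixture(scope="session")
def smad_model():
    return build_model("SMAD_ONLY")


@pytest.fixture(scope="session")
def cal_params():
    """Packaged calibrated full-model parameter set."""
    return calibrated_params()


@pytest.fixture(scope="session")
def center_params():
    return design_center()


@pytest.fixture(scope="session")
def cal_basal(full_model, cal_params):
    return basal_state(full_model, cal_params)


def random_in_bounds(params, rng, names=None):
    """Log-uniform draw inside the prior box of a ParameterSet."""
    from snailrelay.params import default_bounds

    bounds = {**default_bounds(params.values), **params.bounds}
    vals = {}
    for k, v in params.values.items():
        lo, hi = bounds.get(k, (v, v))
        if names is not None and k not in names:
            vals[k] = v
        else:
            vals[k] = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
    return params.__class__(vals, name="random")
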