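import numpy as np
import pytest

from nlddm import DdmParams, NlddmParams
from nlddm.likelihood import FitOptions


@pytest.fixture
def nlddm_default() -> NlddmParams:
    """The reference double-well geometry used throughout the figures."""
    return NlddmParams(k=1.0, a=1.0, z=0.0, sigma=0.3)


@pytest.fixture
def ddm_default() -> DdmParams:
    """DDM simulation defaults of the correlation study."""
    return DdmParams(nu=0.2, B=1.0, x0=0.0, sz=0.0, t_nd=0.3, sigma=0.3)


@pytest.fixture
def fast_fit_options() -> FitOptions:
    """Deliberately small optimizer budget for smoke-level fits."""
    return FitOptions(nx=80, dt=0.006, de_maxiter=6, popsize=6, polish_maxfev=200)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
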