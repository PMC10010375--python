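import numpy as np
import pytest

from dlgrowth.core import DLParams
from dlgrowth.pk import weekly_protocol


@pytest.fixture
def dl_params() -> DLParams:
    """Published CDX population values of the diffusion-limited model."""
    return DLParams(lambda_net=0.12, lambda_nec=0.05, k_drug=5.7e-3, R_c=0.41, V0=0.25)


@pytest.fixture
def protocol1():
    """Weekly 50 mg/kg CPT-11 on days 1, 8, 15."""
    return weekly_protocol(1)


@pytest.fixture
def day_grid():
    return np.linspace(0.0, 30.0, 61)
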