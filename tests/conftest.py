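import numpy as np
import pytest

from ryrcicr.model_core import BindingModelParams
from ryrcicr.synthetic_data import gen_two_domain_fixture


@pytest.fixture
def wt_params() -> BindingModelParams:
    """Wild-type-like biphasic parameter set (pCa50 4.79, nA 2, nI 1, KI 1 mM)."""
    return BindingModelParams.from_pk(Amax=0.4, pKA=4.79, pKI=3.0, nA=2.0, nI=1.0)


@pytest.fixture(scope="session")
def two_domain_files(tmp_path_factory):
    """Toy two-domain coordinate fixture with a known 2.0 A rigid shift."""
    out = tmp_path_factory.mktemp("fixture")
    paths = gen_two_domain_fixture(out, shift=(2.0, 0.0, 0.0), seed=1)
    return paths
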