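import warnings

import pytest

from raftpart import load_asa_scale, load_kd_scale, trlat_record
from raftpart.model import ModelParams, default_params


@pytest.fixture(scope="session")
def asa_scale():
    return load_asa_scale()


@pytest.fixture(scope="session")
def kd_scale():
    return load_kd_scale()


@pytest.fixture(scope="session")
def trlat():
    return trlat_record()


@pytest.fixture(scope="session")
def params():
    """Shipped default parameters (placeholder warning silenced)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return default_params()


@pytest.fixture()
def simple_params():
    """Round-number parameters for arithmetic-oracle tests."""
    return ModelParams(
        delta_gamma=1.0, dG_palm=-0.5, B_LP=1.0, d_lo=3.0, d_ld=2.0,
        temperature=300.0, dG_ex=0.25,
    )
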