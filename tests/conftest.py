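import numpy as np
import pytest

from btksim import PKParameters, PDParameters
from btksim.population import IndividualParameters


@pytest.fixture
def pk_typical():
    return PKParameters()


@pytest.fixture
def pd_slow():
    """Typical PD with the slow (60 h) BTK half-life."""
    return PDParameters()


@pytest.fixture
def pd_fast():
    return PDParameters(t_half_btk=24.0)


def individual_from_typical(pk: PKParameters, pd_: PDParameters,
                            n: int = 1) -> IndividualParameters:
    """Engine-ready single-subject batch mirroring the typical parameters."""
    ones = np.ones(n)
    return IndividualParameters(
        cl_f=pk.cl_f * ones, v2=pk.v2 * ones, v3=pk.v3 * ones, q_f=pk.q_f * ones,
        ka=pk.ka * ones, tlag=pk.tlag * ones, d_zero=pk.d_zero() * ones,
        f1=pk.f1() * ones, btk0=pd_.btk0 * ones, t_half_btk=pd_.t_half_btk * ones,
        kon=pd_.kon * ones, koff=pd_.koff * ones, kinact=pd_.kinact * ones,
        fu=pd_.fu, mw=pd_.mw,
    )


@pytest.fixture
def typical_individual(pk_typical, pd_slow):
    return individual_from_typical(pk_typical, pd_slow)
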