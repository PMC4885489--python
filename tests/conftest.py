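import numpy as np
import pytest

from cypinduct.calibration import reference_set
from cypinduct.pbpk import SimOptions, SystemParameters
from cypinduct.synthetic import make_compound_profile, victim_profile
from cypinduct.trial import CVConfig


@pytest.fixture(scope="session")
def system():
    return SystemParameters()


@pytest.fixture(scope="session")
def fast_opts():
    """Solver settings for population runs (ratio-accurate to <0.1%)."""
    return SimOptions(rtol=1e-4, atol=1e-7)


@pytest.fixture(scope="session")
def tight_opts():
    return SimOptions(rtol=1e-7, atol=1e-10)


@pytest.fixture(scope="session")
def midazolam():
    return victim_profile("midazolam")


@pytest.fixture(scope="session")
def rifampicin_model():
    """Factory: rifampicin-like perpetrator under a given induction scenario."""
    def make(model: str):
        return make_compound_profile("rifampicin_like",
                                     induction=reference_set(model))
    return make


@pytest.fixture(scope="session")
def no_cv():
    """Population variability switched off (reference subject)."""
    return CVConfig(cv_cyp3a4_h=0, cv_cyp3a4_g=0, cv_clu=0, cv_ka=0,
                    cv_vss=0, cv_qh=0, bw_cv=0)
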