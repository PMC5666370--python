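import pytest

from venompep.example_data import example_precursors, observed_venom_masses
from venompep.precursor import enumerate_mature_forms


@pytest.fixture(scope="session")
def plp_precursors():
    return example_precursors()


@pytest.fixture(scope="session")
def plp_candidates(plp_precursors):
    cands = []
    for rec in plp_precursors:
        cands.extend(enumerate_mature_forms(rec))
    return cands


@pytest.fixture(scope="session")
def venom_observed():
    return observed_venom_masses()
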