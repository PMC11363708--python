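import datetime as dt

import pytest

from dmia import fixtures as fx
from dmia.fhir_model import PatientIdentity


@pytest.fixture(scope="session")
def spec():
    return fx.FixtureSpec(seed=0)


@pytest.fixture(scope="session")
def questionnaire(spec):
    return fx.gen_questionnaire(spec)


@pytest.fixture(scope="session")
def kb(spec):
    return fx.gen_kb(spec)


@pytest.fixture
def task(questionnaire):
    """A fresh requested task (tasks are mutated by the engine)."""
    return fx.gen_task(questionnaire)


@pytest.fixture(scope="session")
def patient():
    return PatientIdentity("Erika Muster", dt.date(1970, 1, 1))


@pytest.fixture(scope="session")
def labeled_queries(spec, kb):
    return fx.gen_labeled_queries(kb, spec)
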