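import pytest

from prioritysim import scenario
from prioritysim.epi import Person


@pytest.fixture(scope="session")
def default_bundle():
    return scenario.make_default_scenario(1)


@pytest.fixture(scope="session")
def treatments(default_bundle):
    return default_bundle.treatments_by_id()


@pytest.fixture()
def small_bundle(default_bundle):
    """Quick-running copy of the default scenario."""
    return scenario.scale_bundle(default_bundle, initial_size=300, horizon_years=1)


def make_person(person_id=0, age_years=30.0, day=0, flags=(), sex="f", alive=True):
    return Person(
        person_id=person_id,
        birth_date=int(day - round(age_years * 365)),
        alive=alive,
        sex=sex,
        flags=set(flags),
    )


@pytest.fixture()
def person_factory():
    return make_person
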