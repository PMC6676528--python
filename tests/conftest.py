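import numpy as np
import pytest

from wgdfrac import (
    Branch,
    Event,
    EventSchedule,
    SpeciationScenario,
    doubling,
    synthesize_dataset,
    tripling,
)


@pytest.fixture
def two_doublings() -> EventSchedule:
    """Two WGDs (u2 = 0.35 then 0.5), observed at the present."""
    return EventSchedule(
        1,
        (
            Event("wgd", 65.0, doubling(0.35)),
            Event("wgd", 30.0, doubling(0.5)),
            Event("observation", 0.0),
        ),
    )


@pytest.fixture
def three_doublings() -> EventSchedule:
    return EventSchedule(
        1,
        (
            Event("wgd", 90.0, doubling(0.25)),
            Event("wgd", 55.0, doubling(0.4)),
            Event("wgd", 20.0, doubling(0.6)),
            Event("observation", 0.0),
        ),
    )


@pytest.fixture
def tripling_speciation() -> SpeciationScenario:
    """Tripling, then speciation under the coupled survival model."""
    return SpeciationScenario(
        1,
        (Event("wgd", 80.0, tripling(0.2)),),
        Event("speciation", 40.0, doubling(0.7)),
        Branch((Event("observation", 0.0),)),
        Branch((Event("observation", 0.0),)),
    )


@pytest.fixture
def tomato_like_scenario() -> SpeciationScenario:
    """Tripling, speciation, then one extra WGD in branch A only."""
    return SpeciationScenario(
        1,
        (Event("wgd", 90.0, tripling(0.25)),),
        Event("speciation", 55.0, doubling(0.6)),
        Branch(
            (Event("wgd", 20.0, doubling(0.75)), Event("observation", 0.0)),
        ),
        Branch((Event("observation", 0.0),)),
    )


@pytest.fixture(scope="session")
def synthetic_two_wgd():
    """Seeded synthetic similarity dataset from a 2-WGD schedule."""
    schedule = EventSchedule(
        1000,
        (
            Event("wgd", 65.0, doubling(0.35)),
            Event("wgd", 30.0, doubling(0.5)),
            Event("observation", 0.0),
        ),
    )
    return synthesize_dataset(schedule, seed=20240, target_pairs=20000)


@pytest.fixture(scope="session")
def synthetic_tripling_speciation():
    """Seeded synthetic ortholog dataset: tripling + speciation."""
    scenario = SpeciationScenario(
        1000,
        (Event("wgd", 80.0, tripling(0.2)),),
        Event("speciation", 40.0, doubling(0.7)),
        Branch((Event("observation", 0.0),)),
        Branch((Event("observation", 0.0),)),
    )
    return synthesize_dataset(scenario, seed=20241, target_pairs=20000)


@pytest.fixture(scope="session")
def synthetic_tomato_like():
    """Seeded synthetic ortholog dataset with one post-speciation WGD."""
    scenario = SpeciationScenario(
        1000,
        (Event("wgd", 90.0, tripling(0.25)),),
        Event("speciation", 55.0, doubling(0.6)),
        Branch((Event("wgd", 20.0, doubling(0.75)), Event("observation", 0.0))),
        Branch((Event("observation", 0.0),)),
    )
    return synthesize_dataset(scenario, seed=20242, target_pairs=20000)
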