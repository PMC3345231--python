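import pytest

from ethexpo import (
    EmissionSchedule,
    ExposureProfile,
    PBPKParameters,
    RoomSpec,
    TSDDScenario,
)

# printed stepwise air means of the original classroom incident evaluation
DAY1_WINDOWS = ((0.0, 3.0, 408.0), (3.0, 6.0, 768.0), (6.0, 8.0, 1108.0))
DAY2_WINDOWS = ((24.0, 27.0, 924.0), (27.0, 30.0, 1224.0), (30.0, 32.0, 1518.0))


@pytest.fixture
def classroom() -> RoomSpec:
    return RoomSpec(volume=116.0, vent_rate=0.08)


@pytest.fixture
def day1_schedule() -> EmissionSchedule:
    return EmissionSchedule.from_pairs([(0.0, 50.4), (3.0, 50.4), (6.0, 50.4)])


@pytest.fixture
def two_day_schedule() -> EmissionSchedule:
    return EmissionSchedule.from_pairs(
        [(t, 50.4) for t in (0.0, 3.0, 6.0, 24.0, 27.0, 30.0)]
    )


@pytest.fixture
def default_params() -> PBPKParameters:
    return PBPKParameters()


@pytest.fixture
def default_scenario() -> TSDDScenario:
    return TSDDScenario()


@pytest.fixture
def day1_exposure() -> ExposureProfile:
    return ExposureProfile(segments=DAY1_WINDOWS)


@pytest.fixture
def two_day_exposure() -> ExposureProfile:
    return ExposureProfile(segments=DAY1_WINDOWS + DAY2_WINDOWS)
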