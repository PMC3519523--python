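import pytest

from llasim import BiologyParams, Intervention, PopulationParams, run_fcm


@pytest.fixture(scope="session")
def bio() -> BiologyParams:
    return BiologyParams()


@pytest.fixture(scope="session")
def pop() -> PopulationParams:
    return PopulationParams()


@pytest.fixture(scope="session")
def untreated_fcm(bio):
    return run_fcm(bio, Intervention.none())


@pytest.fixture(scope="session")
def scenario_interventions():
    """Spanning set of treatment scenarios used by several suites."""
    return {
        "none": Intervention.none(),
        "instant_kill": Intervention.instant_kill(0.8),
        "instant_kill_repellent": Intervention.instant_kill(0.8, repellency=0.5),
        "biopesticide_early": Intervention.biopesticide(0.8, 3, 0.72),
        "biopesticide_late": Intervention.biopesticide(0.8, 9, 0.91),
        "biopesticide_differential": Intervention.biopesticide(
            0.8, 3, 0.72, uninfected_daily_mortality=0.1
        ),
    }
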