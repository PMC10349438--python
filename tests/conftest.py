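import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sociorank.ethogram import DEFAULT_ETHOGRAM, EventLog, InteractionEvent
from sociorank.pipeline import run_study
from sociorank.simulate import SimulationConfig, simulate_study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_log(rows, roster=None):
    """rows: (period, session, author, receptor, behavior) tuples."""
    events = tuple(InteractionEvent(*r) for r in rows)
    if roster is None:
        roster = {a for e in events for a in (e.author, e.receptor)}
    return EventLog(events, tuple(roster))


@pytest.fixture(scope="session")
def toy_log():
    """Four agonistic + one affiliative events between A and B, pre period."""
    return make_log(
        [
            ("pre", 1, "A", "B", "mount"),
            ("pre", 1, "A", "B", "fight"),
            ("pre", 2, "A", "B", "headbutt"),
            ("pre", 3, "B", "A", "headbutt"),
            ("pre", 4, "B", "A", "head-play"),
        ]
    )


@pytest.fixture(scope="session")
def default_study():
    """One default-condition synthetic herd (14 bulls, both periods)."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_report(default_study):
    return run_study(default_study.event_log, default_study.covariates)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
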