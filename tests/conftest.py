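import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_session():
    """A tiny hand-built session with all three channels."""
    from hbregimes.io_sessions import RawChannel, Session

    t = np.arange(0.0, 120.0, 4.0)
    return Session(
        session_id="tiny",
        date="2021-06-18",
        age=57.0,
        vo2max=36.7,
        channels={
            "hr": RawChannel("hr", t, 160 + np.sin(t / 10.0)),
            "speed": RawChannel("speed", t + 1.0, 2.5 + 0.1 * np.cos(t / 7.0)),
            "altitude": RawChannel("altitude", t + 0.5, 100 + t / 30.0),
        },
    )


@pytest.fixture(scope="session")
def balanced_fit():
    """One analysed balanced-plan session, shared across tests (slow)."""
    import hbregimes as hb

    plan = hb.make_balanced_plan(seed=3)
    session, truth = hb.generate_session(plan)
    result = hb.RunningSessionModel(session).fit(seed=0)
    return plan, session, truth, result
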