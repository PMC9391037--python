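import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fetalvoc.events import MovementEvent, MovementUnit, Session

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_event(onset, offset, kind="orofacial", partial=False, session="s1"):
    return MovementEvent(
        session_id=session,
        pregnancy_id="P1",
        gestational_day=100,
        kind=kind,
        onset=onset,
        offset=offset,
        partial=partial,
    )


def make_unit(onset, offset, kind="orofacial", partial=False, session="s1"):
    return MovementUnit((make_event(onset, offset, kind, partial, session),))


def make_session(
    oro_intervals=(),
    head_intervals=(),
    visible_time_s=600.0,
    session="s1",
    pregnancy="P1",
    day=100,
):
    return Session(
        session_id=session,
        pregnancy_id=pregnancy,
        gestational_day=day,
        visible_time_s=visible_time_s,
        orofacial_units=[
            make_unit(a, b, "orofacial", session=session) for a, b in oro_intervals
        ],
        head_units=[
            make_unit(a, b, "head", session=session) for a, b in head_intervals
        ],
    )


@pytest.fixture(scope="session")
def default_cohort():
    from fetalvoc.synthetic import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec(), seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
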