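import datetime as dt

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from chimpwelfare.core import ChimpProfile, WellnessResponse, WoundEvent
from chimpwelfare.defaults import WELLNESS_PARAMETERS

D0 = dt.date(2022, 1, 1)


@pytest.fixture
def roster():
    return [
        ChimpProfile("Kasey", "Kasey", "M", dt.date(1988, 1, 1), "G1"),
        ChimpProfile("Latoya", "Latoya", "F", dt.date(1991, 6, 1), "G1"),
        ChimpProfile("Tessa", "Tessa", "F", dt.date(1998, 3, 1), "G1"),
        ChimpProfile("Blue", "Blue", "M", dt.date(1985, 5, 1), "G2"),
    ]


def make_response(chimp="Kasey", observer="obs1", department="behavior",
                  date=D0, **scores):
    params = {p: 0 for p in WELLNESS_PARAMETERS}
    params.update(scores)
    return WellnessResponse(chimp_id=chimp, observer=observer,
                            department=department, date=date, parameters=params)


def make_wound(wid, chimp="Kasey", day=0, grade=1, kind="initial"):
    return WoundEvent(wound_id=wid, chimp_id=chimp,
                      date=D0 + dt.timedelta(days=day), grade=grade, event_kind=kind)
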