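import datetime as dt

import pytest

from vaxsignal.reports import Report
from vaxsignal.simulate import table_like_fixture


@pytest.fixture(scope="session")
def fixture_db():
    """The standard 8-vaccine, ~2000-report synthetic database."""
    return table_like_fixture()


def make_report(vaccine="V1", event="E1", *, rid="R1", date=dt.date(2009, 6, 1),
                sex="F", age=30.0, region="EU", tto=None):
    return Report(report_id=rid, receipt_date=date, vaccine=vaccine, event=event,
                  sex=sex, age_years=age, region=region, tto_days=tto)


@pytest.fixture
def tiny_reports():
    """Three vaccines x three events with hand-picked TTO values."""
    rows = []
    i = 0
    for v, e, tto in [
        ("V1", "E1", 0), ("V1", "E1", 5), ("V1", "E1", 30),
        ("V1", "E2", 10), ("V1", "E2", None),
        ("V1", "E3", 40),
        ("V2", "E1", 3), ("V2", "E1", 7),
        ("V2", "E2", 60),
        ("V3", "E1", 15), ("V3", "E3", 2), ("V3", "E3", 90),
    ]:
        i += 1
        rows.append(make_report(v, e, rid=f"R{i:03d}",
                                date=dt.date(2009, 1, 1) + dt.timedelta(days=i),
                                tto=tto))
    return rows
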