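import datetime as dt

import pytest

from comorbnet import ComorbidityNetwork, PatientRecord


def make_record(id="P1", sex="F", birth="1960-05-10", admission="2013-03-01 09:00",
                discharge="2013-03-07 10:00", codes=("J46", "I10", "J18.9")):
    return PatientRecord(
        id=id,
        sex=sex,
        birth_date=dt.date.fromisoformat(birth),
        admission_ts=dt.datetime.fromisoformat(admission),
        discharge_ts=dt.datetime.fromisoformat(discharge),
        icd_codes=frozenset(codes),
    )


@pytest.fixture
def two_triangles():
    """Two disjoint unit-weight triangles: the classic 2-community graph."""
    net = ComorbidityNetwork()
    for u, v in [("A", "B"), ("B", "C"), ("A", "C"),
                 ("D", "E"), ("E", "F"), ("D", "F")]:
        net.add_edge(u, v)
    return net


@pytest.fixture
def records_csv(tmp_path):
    """Write a small records file and return its path."""

    def _write(rows, header="id,sex,birth_date,admission,discharge,codes"):
        path = tmp_path / "records.csv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return _write
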