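import pytest

from pvsignal.faers_io import DrugEntry, ReportRecord, parse_partial_date
from pvsignal.preprocess import FilterConfig

TARGET = "10038907"
OTHER = "10019211"


def make_record(
    caseid="100",
    primaryid=None,
    fda="20230101",
    event=None,
    occupation="physician",
    drugs=(("drugx", "primary_suspect", None),),
    reactions=(TARGET,),
    **kwargs,
):
    return ReportRecord(
        primaryid=primaryid or caseid + "1",
        caseid=caseid,
        fda_date=parse_partial_date(fda),
        event_date=parse_partial_date(event) if event else None,
        reporter_occupation=occupation,
        drugs=[
            DrugEntry(
                name=n, role=role,
                therapy_start=parse_partial_date(start) if start else None,
                seq=str(i + 1),
            )
            for i, (n, role, start) in enumerate(drugs)
        ],
        reactions=list(reactions),
        **kwargs,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def config():
    return FilterConfig(target_pts=frozenset({TARGET}))


@pytest.fixture
def four_case_universe(config):
    """Exhaustive 2x2 universe: {drugx+event, drugx+other, drugy+event,
    drugy+other} -> drugx table is (1, 1, 1, 1)."""
    from pvsignal.preprocess import deduplicate, select_event_cases

    records = [
        make_record(caseid="1", drugs=(("drugx", "primary_suspect", None),),
                    reactions=(TARGET,)),
        make_record(caseid="2", drugs=(("drugx", "primary_suspect", None),),
                    reactions=(OTHER,)),
        make_record(caseid="3", drugs=(("drugy", "primary_suspect", None),),
                    reactions=(TARGET,)),
        make_record(caseid="4", drugs=(("drugy", "primary_suspect", None),),
                    reactions=(OTHER,)),
    ]
    return select_event_cases(deduplicate(records), config)
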