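import numpy as np
import pytest

from iccpool.study_io import ICCRecord, Study, StudyTable, load_table1


@pytest.fixture(scope="session")
def table1() -> StudyTable:
    return load_table1()


def make_table(records: list[tuple], study_weights: dict[str, float] | None = None) -> StudyTable:
    """Build a StudyTable from (study_id, outcome_id, icc, n, k, weight) tuples."""
    study_weights = study_weights or {}
    order: list[str] = []
    by_study: dict[str, list[ICCRecord]] = {}
    for sid, oid, icc, n, k, w in records:
        if sid not in order:
            order.append(sid)
            by_study[sid] = []
        by_study[sid].append(ICCRecord(sid, oid, icc, n, k, w))
    studies = tuple(
        Study(sid, study_weights.get(sid, 1.0), tuple(by_study[sid])) for sid in order
    )
    t = StudyTable(studies)
    t.validate()
    return t


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
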