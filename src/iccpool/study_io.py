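"""Data model and delimited-text I/O for tables of external ICC estimates.

A *study table* collects intracluster correlation coefficient (ICC)
estimates extracted from previously published cluster-randomised trials,
one row per outcome within a study.  Each record carries the point
estimate ``icc_hat``, the total number of participants ``n_participants``
and number of clusters ``n_clusters`` of the source trial (which determine
the sampling variance of the estimate), and a relevance weight in (0, 1]
expressing how pertinent the outcome is to the trial being planned.
Study-level relevance weights live on the :class:`Study` container.

The on-disk representation is a flat UTF-8 CSV with a header row and
columns ``study_id, outcome_id, label, icc, n, k, study_weight,
outcome_weight``.  The study weight is repeated on each of the study's
rows; the first occurrence wins and a conflicting repeat is an error.
Weight columns are optional and default to 1.0 (fully relevant).

A 34-record table of stroke-trial ICC estimates from 16 studies is
bundled as a fixture, loadable with :func:`load_table1`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ICCRecord",
    "Study",
    "StudyTable",
    "StudyTableError",
    "read_study_table",
    "write_study_table",
    "load_table1",
    "with_weights",
]

CSV_COLUMNS = [
    "study_id",
    "outcome_id",
    "label",
    "icc",
    "n",
    "k",
    "study_weight",
    "outcome_weight",
]

REQUIRED_COLUMNS = ["study_id", "outcome_id", "icc", "n", "k"]


class StudyTableError(ValueError):
    """Raised for malformed files or records violating table invariants."""


@dataclass(frozen=True)
class ICCRecord:
    """One external ICC estimate: an outcome within a source study."""

    study_id: str
    outcome_id: str
    icc_hat: float
    n_participants: int
    n_clusters: int
    outcome_weight: float = 1.0
    label: str = ""

    def validate(self) -> None:
        rid = f"record ({self.study_id}, {self.outcome_id})"
        if self.n_clusters < 2:
            raise StudyTableError(f"{rid}: number of clusters k={self.n_clusters} must be >= 2")
        if self.n_participants <= self.n_clusters:
            raise StudyTableError(
                f"{rid}: n={self.n_participants} must exceed k={self.n_clusters}"
            )
        if not (0.0 <= self.icc_hat < 1.0):
            raise StudyTableError(f"{rid}: icc={self.icc_hat} must lie in [0, 1)")
        if not (0.0 < self.outcome_weight <= 1.0):
            raise StudyTableError(
                f"{rid}: outcome_weight={self.outcome_weight} must lie in (0, 1]"
            )


@dataclass(frozen=True)
class Study:
    """A source study and its outcome-level ICC records."""

    study_id: str
    study_weight: float = 1.0
    records: tuple[ICCRecord, ...] = ()

    def validate(self) -> None:
        if not self.records:
            raise StudyTableError(f"study {self.study_id}: at least one record required")
        if not (0.0 < self.study_weight <= 1.0):
            raise StudyTableError(
                f"study {self.study_id}: study_weight={self.study_weight} must lie in (0, 1]"
            )
        for rec in self.records:
            if rec.study_id != self.study_id:
                raise StudyTableError(
                    f"study {self.study_id}: record has mismatched study_id {rec.study_id}"
                )
            rec.validate()


@dataclass(frozen=True)
class StudyTable:
    """An ordered collection of studies with ICC records."""

    studies: tuple[Study, ...] = ()

    def validate(self) -> None:
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise StudyTableError(f"duplicate study_id(s): {dup}")
        for s in self.studies:
            s.validate()

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_records(self) -> int:
        return sum(len(s.records) for s in self.studies)

    def iter_records(self) -> Iterator[ICCRecord]:
        for s in self.studies:
            yield from s.records

    @property
    def records(self) -> tuple[ICCRecord, ...]:
        return tuple(self.iter_records())

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the CSV column layout (one row per record)."""
        rows = []
        for s in self.studies:
            for r in s.records:
                rows.append(
                    {
                        "study_id": s.study_id,
                        "outcome_id": r.outcome_id,
                        "label": r.label,
                        "icc": r.icc_hat,
                        "n": r.n_participants,
                        "k": r.n_clusters,
                        "study_weight": s.study_weight,
                        "outcome_weight": r.outcome_weight,
                    }
                )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def arrays(self) -> dict[str, np.ndarray]:
        """Pooled record-level arrays used by the model and summaries.

        Returns ``icc_hat``, ``n``, ``k``, ``outcome_weight`` (length =
        number of records), ``study_weight`` (length = number of studies)
        and ``study_index`` mapping each record to its study position.
        """
        icc, n, k, w_l, sidx = [], [], [], [], []
        w_s = []
        for i, s in enumerate(self.studies):
            w_s.append(s.study_weight)
            for r in s.records:
                icc.append(r.icc_hat)
                n.append(r.n_participants)
                k.append(r.n_clusters)
                w_l.append(r.outcome_weight)
                sidx.append(i)
        return {
            "icc_hat": np.asarray(icc, dtype=float),
            "n": np.asarray(n, dtype=float),
            "k": np.asarray(k, dtype=float),
            "outcome_weight": np.asarray(w_l, dtype=float),
            "study_weight": np.asarray(w_s, dtype=float),
            "study_index": np.asarray(sidx, dtype=int),
        }


def _parse_row(row: pd.Series, line_no: int) -> tuple[str, str, str, float, int, int, float, float]:
    try:
        study_id = str(row["study_id"])
        outcome_id = str(row["outcome_id"])
        label = "" if "label" not in row or pd.isna(row["label"]) else str(row["label"])
        icc = float(row["icc"])
        n = int(row["n"])
        k = int(row["k"])
        sw = row.get("study_weight", 1.0)
        ow = row.get("outcome_weight", 1.0)
        sw = 1.0 if pd.isna(sw) else float(sw)
        ow = 1.0 if pd.isna(ow) else float(ow)
    except (TypeError, ValueError, KeyError) as exc:
        raise StudyTableError(f"malformed row at line {line_no}: {exc}") from exc
    if math.isnan(icc) or n != float(row["n"]) or k != float(row["k"]):
        raise StudyTableError(f"malformed row at line {line_no}: non-numeric or fractional count")
    return study_id, outcome_id, label, icc, n, k, sw, ow


def read_study_table(path: str | Path) -> StudyTable:
    """Read and validate a study table from a CSV file.

    Rows are grouped by ``study_id`` preserving file order.  Missing
    weight columns (or blank weight cells) default to 1.0.  Weights of
    exactly zero are rejected: the hierarchical model divides variances
    by them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"study table not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"study_id": str, "outcome_id": str, "label": str})
    except Exception as exc:  # noqa: BLE001 - surface parser failures uniformly
        raise StudyTableError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StudyTableError(f"{path}: missing required column(s) {missing}")

    order: list[str] = []
    weights: dict[str, tuple[float, int]] = {}
    records: dict[str, list[ICCRecord]] = {}
    for i, (_, row) in enumerate(df.iterrows()):
        line_no = i + 2  # header is line 1
        study_id, outcome_id, label, icc, n, k, sw, ow = _parse_row(row, line_no)
        rec = ICCRecord(study_id, outcome_id, icc, n, k, ow, label)
        try:
            rec.validate()
        except StudyTableError as exc:
            raise StudyTableError(f"line {line_no}: {exc}") from exc
        if study_id not in order:
            order.append(study_id)
            weights[study_id] = (sw, line_no)
            records[study_id] = []
        else:
            first_sw, first_line = weights[study_id]
            if "study_weight" in df.columns and not pd.isna(row.get("study_weight")):
                if sw != first_sw:
                    raise StudyTableError(
                        f"line {line_no}: study_weight {sw} for study {study_id} "
                        f"conflicts with {first_sw} at line {first_line}"
                    )
        records[study_id].append(rec)

    studies = tuple(
        Study(sid, study_weight=weights[sid][0], records=tuple(records[sid])) for sid in order
    )
    table = StudyTable(studies)
    table.validate()
    return table


def write_study_table(table: StudyTable, path: str | Path) -> None:
    """Write a study table as CSV; ``read_study_table`` round-trips it."""
    table.validate()
    df = table.to_frame()
    df.to_csv(Path(path), index=False)


def load_table1() -> StudyTable:
    """Load the bundled 16-study, 34-record stroke-trial ICC table."""
    with resources.as_file(resources.files("iccpool.data") / "table1_icc.csv") as p:
        return read_study_table(p)


def with_weights(
    table: StudyTable,
    study_weights: Mapping[str, float] | None = None,
    outcome_weights: Mapping[tuple[str, str], float] | None = None,
) -> StudyTable:
    """Return a copy of ``table`` with relevance weights replaced.

    ``study_weights`` maps study_id to the pooled study weight;
    ``outcome_weights`` maps (study_id, outcome_id) to the pooled outcome
    weight.  Entries not present keep their existing value.
    """
    study_weights = dict(study_weights or {})
    outcome_weights = dict(outcome_weights or {})
    studies = []
    for s in table.studies:
        recs = tuple(
            replace(r, outcome_weight=outcome_weights.get((s.study_id, r.outcome_id), r.outcome_weight))
            for r in s.records
        )
        studies.append(
            Study(s.study_id, study_weights.get(s.study_id, s.study_weight), recs)
        )
    out = StudyTable(tuple(studies))
    out.validate()
    return out


def read_weight_file(path: str | Path) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Read a user-supplied weight CSV.

    Columns: ``study_id``, optional ``outcome_id``, ``weight``.  Rows
    without an ``outcome_id`` set the study-level weight; rows with one
    set the outcome-level weight.
    """
    df = pd.read_csv(Path(path), dtype={"study_id": str, "outcome_id": str})
    if "study_id" not in df.columns or "weight" not in df.columns:
        raise StudyTableError(f"{path}: weight file needs study_id and weight columns")
    sw: dict[str, float] = {}
    ow: dict[tuple[str, str], float] = {}
    for _, row in df.iterrows():
        w = float(row["weight"])
        if "outcome_id" in df.columns and not pd.isna(row.get("outcome_id")):
            ow[(str(row["study_id"]), str(row["outcome_id"]))] = w
        else:
            sw[str(row["study_id"])] = w
    return sw, ow
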