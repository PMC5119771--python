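"""Study-level records: domain types, CSV ingest/egress, arm summaries.

The unit of data throughout the package is the *aggregate study record*:
one row per study (or per published subgroup data point) carrying the
group's size, demographics, mean resting and maximal heart rates and mean
VO2peak. A packaged fixture reproduces the descriptive table of 40
large-scale treadmill studies (20 with gas-exchange-measured VO2peak, 20
with equation-predicted VO2peak); the source publications do not print the
per-study heart-rate and VO2 columns, so those cells ship empty.

Oxygen uptake is stored internally in METs. Tables may declare values in
mL O2·kg⁻¹·min⁻¹ via the ``vo2_units`` column; such values are divided by
3.5 on ingest so all downstream arithmetic is in METs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, RecordValidationError, SchemaError
from .model import ML_PER_MET

__all__ = [
    "Arm", "RailSupport", "Vo2Source", "StudyRecord", "ArmDescriptives",
    "read_study_table", "write_records", "summarize_arm", "load_table1",
    "COLUMNS",
]


class Arm(str, enum.Enum):
    """Which comparison arm a study belongs to."""

    MEASURED = "measured"   #: VO2peak measured by gas-exchange analysis
    PREDICTED = "predicted"  #: VO2peak predicted from treadmill parameters


class RailSupport(str, enum.Enum):
    """Handrail-support descriptor as reported by the source study."""

    NOT_STATED = "not_stated"
    NOT_PERMITTED = "not_permitted"
    DISCOURAGED = "discouraged"
    LIGHT_SUPPORT = "light_support"


class Vo2Source(str, enum.Enum):
    """How the study obtained its VO2peak value."""

    MEASURED = "measured"
    EQUATION = "equation"


#: Required CSV header, in canonical order.
COLUMNS: tuple[str, ...] = (
    "study_id", "first_author", "year", "arm", "n", "age_mean", "male_pct",
    "category", "protocol", "rail_support", "hr_rest", "hr_max", "vo2peak",
    "vo2_units", "vo2_source",
)


@dataclass(frozen=True)
class StudyRecord:
    """Aggregate descriptors for one study or subgroup data point.

    Optional fields (``hr_rest``, ``hr_max``, ``vo2peak``, ``vo2_source``)
    are ``None`` when the source publication does not print them; they are
    never imputed. ``vo2peak`` is always in METs.
    """

    study_id: str
    first_author: str
    year: int
    arm: Arm
    n: int
    age_mean: float
    male_pct: float
    category: str
    protocol: str
    rail_support: RailSupport = RailSupport.NOT_STATED
    hr_rest: float | None = None
    hr_max: float | None = None
    vo2peak: float | None = None
    vo2_source: Vo2Source | None = None

    def __post_init__(self) -> None:
        def bad(field: str, msg: str) -> RecordValidationError:
            return RecordValidationError(
                f"study {self.study_id!r}: {msg}", study_id=self.study_id, field=field
            )

        if not isinstance(self.n, (int, np.integer)) or self.n < 1:
            raise bad("n", f"n must be a positive integer, got {self.n!r}")
        if self.year < 1900:
            raise bad("year", f"year must be >= 1900, got {self.year!r}")
        if not 0 <= self.male_pct <= 100:
            raise bad("male_pct", f"male_pct must lie in [0, 100], got {self.male_pct!r}")
        if self.hr_rest is not None and self.hr_max is not None:
            if not (20 < self.hr_rest < self.hr_max < 250):
                raise bad(
                    "hr_rest",
                    f"heart rates must satisfy 20 < hr_rest < hr_max < 250, "
                    f"got rest={self.hr_rest!r}, max={self.hr_max!r}",
                )
        if self.vo2peak is not None and not self.vo2peak > 0:
            raise bad("vo2peak", f"vo2peak must be positive, got {self.vo2peak!r}")


@dataclass(frozen=True)
class ArmDescriptives:
    """Descriptive summary of every study in one arm.

    ``n_median`` is the midpoint average of the two central order
    statistics for even study counts. Demographics are n-weighted means by
    default (see :func:`summarize_arm`).
    """

    arm: Arm
    n_studies: int
    n_total: int
    n_min: int
    n_max: int
    n_median: float
    age_weighted_mean: float
    male_pct_weighted: float

    def __post_init__(self) -> None:
        assert self.n_min <= self.n_median <= self.n_max
        assert self.n_total >= self.n_max


def _parse_float(cell: str, *, row: str, field: str) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise RecordValidationError(
            f"study {row!r}: field {field!r} is not numeric: {cell!r}",
            study_id=row, field=field,
        ) from None


def _parse_int(cell: str, *, row: str, field: str) -> int:
    value = _parse_float(cell, row=row, field=field)
    if value is None or value != int(value):
        raise RecordValidationError(
            f"study {row!r}: field {field!r} must be an integer, got {cell!r}",
            study_id=row, field=field,
        )
    return int(value)


def _parse_enum(cell: str, cls, *, row: str, field: str):
    try:
        return cls(cell)
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise RecordValidationError(
            f"study {row!r}: field {field!r} must be one of {{{valid}}}, got {cell!r}",
            study_id=row, field=field,
        ) from None


def read_study_table(path: str | Path, delimiter: str = ",") -> list[StudyRecord]:
    """Read and validate a delimited study table.

    The header must name every column in :data:`COLUMNS` (extra columns are
    ignored). Row order is preserved. Values flagged ``ml_kg_min`` in the
    ``vo2_units`` column are converted to METs on ingest (divide by 3.5).

    Raises
    ------
    SchemaError
        If a required column is missing from the header.
    RecordValidationError
        If any row violates a :class:`StudyRecord` invariant; the error
        names the study_id and field.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                     encoding="utf-8")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    for _, row in df.iterrows():
        sid = row["study_id"]
        vo2 = _parse_float(row["vo2peak"], row=sid, field="vo2peak")
        units = row["vo2_units"]
        if vo2 is not None:
            if units == "ml_kg_min":
                vo2 /= ML_PER_MET
            elif units not in ("", "METs"):
                raise RecordValidationError(
                    f"study {sid!r}: unknown vo2_units {units!r} "
                    "(expected 'METs' or 'ml_kg_min')",
                    study_id=sid, field="vo2_units",
                )
        source = row["vo2_source"]
        records.append(StudyRecord(
            study_id=sid,
            first_author=row["first_author"],
            year=_parse_int(row["year"], row=sid, field="year"),
            arm=_parse_enum(row["arm"], Arm, row=sid, field="arm"),
            n=_parse_int(row["n"], row=sid, field="n"),
            age_mean=_parse_float(row["age_mean"], row=sid, field="age_mean"),
            male_pct=_parse_float(row["male_pct"], row=sid, field="male_pct"),
            category=row["category"],
            protocol=row["protocol"],
            rail_support=_parse_enum(row["rail_support"], RailSupport,
                                     row=sid, field="rail_support"),
            hr_rest=_parse_float(row["hr_rest"], row=sid, field="hr_rest"),
            hr_max=_parse_float(row["hr_max"], row=sid, field="hr_max"),
            vo2peak=vo2,
            vo2_source=(_parse_enum(source, Vo2Source, row=sid, field="vo2_source")
                        if source else None),
        ))
    return records


def write_records(records: Iterable[StudyRecord], path: str | Path,
                  delimiter: str = ",") -> None:
    """Write records to a delimited table; inverse of :func:`read_study_table`.

    Absent optional fields are written as empty cells, never zeros.
    VO2peak is written in METs with the units flag set accordingly.
    """
    rows = []
    for r in records:
        rows.append({
            "study_id": r.study_id, "first_author": r.first_author,
            "year": r.year, "arm": r.arm.value, "n": r.n,
            "age_mean": r.age_mean, "male_pct": r.male_pct,
            "category": r.category, "protocol": r.protocol,
            "rail_support": r.rail_support.value,
            "hr_rest": "" if r.hr_rest is None else r.hr_rest,
            "hr_max": "" if r.hr_max is None else r.hr_max,
            "vo2peak": "" if r.vo2peak is None else repr(r.vo2peak),
            "vo2_units": "" if r.vo2peak is None else "METs",
            "vo2_source": "" if r.vo2_source is None else r.vo2_source.value,
        })
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    df.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def summarize_arm(records: Sequence[StudyRecord], arm: Arm | str,
                  weighted: bool = True) -> ArmDescriptives:
    """Descriptive summary (totals, range, median, demographics) of one arm.

    Parameters
    ----------
    records
        Any mix of records; only those in ``arm`` are summarised.
    arm
        Which arm to select.
    weighted
        If True (default) age and male % are n-weighted means; if False,
        each study counts once.

    Raises
    ------
    EmptySelectionError
        If no record belongs to the requested arm.
    """
    arm = Arm(arm)
    members = [r for r in records if r.arm is arm]
    if not members:
        raise EmptySelectionError(f"no records in arm {arm.value!r}")
    ns = np.array([r.n for r in members], dtype=float)
    ages = np.array([r.age_mean for r in members], dtype=float)
    males = np.array([r.male_pct for r in members], dtype=float)
    w = ns if weighted else np.ones_like(ns)
    return ArmDescriptives(
        arm=arm,
        n_studies=len(members),
        n_total=int(ns.sum()),
        n_min=int(ns.min()),
        n_max=int(ns.max()),
        n_median=float(np.median(ns)),
        age_weighted_mean=float(np.average(ages, weights=w)),
        male_pct_weighted=float(np.average(males, weights=w)),
    )


def load_table1() -> list[StudyRecord]:
    """Load the packaged 40-study descriptive fixture.

    Twenty measured-arm and twenty predicted-arm studies with sample size,
    age, sex, diagnosis category, protocol and rail-support descriptors;
    heart-rate and VO2 cells are empty because the source table does not
    print them.
    """
    with resources.as_file(resources.files("hrindex.data") / "table1.csv") as p:
        return read_study_table(p)


def set_heart_rates(record: StudyRecord, hr_rest: float, hr_max: float) -> StudyRecord:
    """Return a copy of ``record`` with heart rates filled in (validated)."""
    return replace(record, hr_rest=hr_rest, hr_max=hr_max)
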