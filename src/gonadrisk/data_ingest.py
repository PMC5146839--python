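"""Count-table I/O, the teaching-hospital cohort fixture, and record preprocessing.

The unit of analysis is a per-disease contingency of case and denominator
counts for the four sex classes of a gonadectomy study: intact female (F),
neutered/spayed female (NF), intact male (M) and neutered/castrated male (NM).
These counts are the sufficient statistics of the hierarchical binomial model
in :mod:`gonadrisk.hier_model`.

Record-level preprocessing implements the status-at-diagnosis rule used in
retrospective neuter studies: a dog neutered only *after* its first confirmed
diagnosis was intact when the disease arose and is counted in the intact
class, while the denominator contribution of undiagnosed dogs follows their
final recorded status.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SexClass",
    "CLASS_ORDER",
    "CountTable",
    "PatientRecord",
    "SchemaError",
    "ValidationError",
    "AmbiguousNeuterError",
    "read_count_tables",
    "write_count_tables",
    "load_cohort_counts",
    "COHORT_TOTAL",
    "COHORT_DISEASES",
    "read_patient_records",
    "write_patient_records",
    "classify_status_at_diagnosis",
    "final_sex_class",
    "aggregate_records",
]

CSV_COLUMNS = ("disease", "sex_class", "cases", "total")

#: Total dogs in the packaged cohort (sum of the four class denominators).
COHORT_TOTAL = 90_090

#: Diseases of the packaged cohort, in publication order.  The first eleven
#: are immune-mediated conditions; pyometra (PYO) is the female-only positive
#: control and carries no male counts.
COHORT_DISEASES = (
    "ATOP", "AIHA", "CMG", "COL", "ADD", "HYPO",
    "IMPA", "ITP", "IBD", "LUP", "PEMC", "PYO",
)


class SchemaError(ValueError):
    """A count-table CSV is missing required columns."""


class ValidationError(ValueError):
    """A row or table violates the count invariants."""


class AmbiguousNeuterError(ValueError):
    """A dog is recorded as neutered but its neuter date is unknown."""


class SexClass(enum.Enum):
    """One of the four sex-by-gonadectomy classes."""

    F = "F"
    NF = "NF"
    M = "M"
    NM = "NM"

    @property
    def is_neutered(self) -> bool:
        return self in (SexClass.NF, SexClass.NM)

    @property
    def is_female(self) -> bool:
        return self in (SexClass.F, SexClass.NF)

    @property
    def intact_counterpart(self) -> "SexClass":
        return SexClass.F if self.is_female else SexClass.M

    @property
    def neutered_counterpart(self) -> "SexClass":
        return SexClass.NF if self.is_female else SexClass.NM

    @classmethod
    def for_sex(cls, sex: str, neutered: bool) -> "SexClass":
        sex = sex.lower()
        if sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
        if sex == "female":
            return cls.NF if neutered else cls.F
        return cls.NM if neutered else cls.M


#: Canonical reporting order of the sex classes.
CLASS_ORDER = (SexClass.F, SexClass.NF, SexClass.M, SexClass.NM)


@dataclass(frozen=True)
class CountTable:
    """Cases and denominators for one disease, by sex class.

    ``cases[c]`` is the number of affected dogs in class ``c`` and
    ``totals[c]`` the number of all dogs in that class (cases + controls).
    Classes absent from both mappings are unavailable for this disease
    (e.g. the male classes for pyometra).
    """

    disease: str
    cases: Mapping[SexClass, int]
    totals: Mapping[SexClass, int]

    def __post_init__(self) -> None:
        if not self.disease:
            raise ValidationError("disease identifier must be non-empty")
        if set(self.cases) != set(self.totals):
            raise ValidationError(
                f"{self.disease}: cases and totals must cover the same classes"
            )
        if not self.cases:
            raise ValidationError(f"{self.disease}: no sex classes available")
        for c in self.cases:
            cases, total = int(self.cases[c]), int(self.totals[c])
            if total <= 0:
                raise ValidationError(
                    f"{self.disease}/{c.value}: total must be positive, got {total}"
                )
            if cases < 0 or cases > total:
                raise ValidationError(
                    f"{self.disease}/{c.value}: need 0 <= cases <= total, "
                    f"got cases={cases}, total={total}"
                )
        # freeze canonical ordering
        object.__setattr__(
            self, "cases", {c: int(self.cases[c]) for c in CLASS_ORDER if c in self.cases}
        )
        object.__setattr__(
            self, "totals", {c: int(self.totals[c]) for c in CLASS_ORDER if c in self.totals}
        )

    @property
    def classes(self) -> tuple[SexClass, ...]:
        """Available sex classes, in canonical order."""
        return tuple(self.cases)

    def has_pair(self, female: bool) -> bool:
        """Whether both classes of the given sex are available."""
        pair = (SexClass.F, SexClass.NF) if female else (SexClass.M, SexClass.NM)
        return all(c in self.cases for c in pair)

    @property
    def n_total(self) -> int:
        return sum(self.totals.values())

    @property
    def n_cases(self) -> int:
        return sum(self.cases.values())


# ---------------------------------------------------------------------------
# count-table CSV I/O


def _tables_from_frame(df: pd.DataFrame, origin: str) -> dict[str, CountTable]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{origin}: missing column(s) {missing}")
    dup = df.duplicated(subset=["disease", "sex_class"], keep=False)
    if dup.any():
        rows = df.loc[dup, ["disease", "sex_class"]].drop_duplicates()
        raise ValidationError(
            f"{origin}: duplicate (disease, sex_class) rows: "
            + ", ".join(f"({r.disease}, {r.sex_class})" for r in rows.itertuples())
        )
    tables: dict[str, CountTable] = {}
    for disease, group in df.groupby("disease", sort=False):
        cases: dict[SexClass, int] = {}
        totals: dict[SexClass, int] = {}
        for row in group.itertuples():
            try:
                sc = SexClass(str(row.sex_class))
            except ValueError:
                raise ValidationError(
                    f"{origin} row {row.Index}: unknown sex_class {row.sex_class!r}"
                ) from None
            try:
                c, n = int(row.cases), int(row.total)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{origin} row {row.Index}: non-integer cases/total"
                ) from None
            if n <= 0 or c < 0 or c > n:
                raise ValidationError(
                    f"{origin} row {row.Index} ({disease}, {sc.value}): "
                    f"need 0 <= cases <= total and total > 0, got {c}/{n}"
                )
            cases[sc], totals[sc] = c, n
        tables[str(disease)] = CountTable(str(disease), cases, totals)
    return tables


def read_count_tables(path) -> dict[str, CountTable]:
    """Read per-disease count tables from a CSV file.

    The schema is fixed: a header row and columns
    ``disease,sex_class,cases,total`` (UTF-8, comma-delimited), with
    ``sex_class`` drawn from {F, NF, M, NM}.  A repeated
    (disease, sex_class) pair is an error, never summed.
    """
    df = pd.read_csv(path, comment="#")
    return _tables_from_frame(df, str(path))


def tables_to_frame(tables: Iterable[CountTable]) -> pd.DataFrame:
    rows = [
        {"disease": t.disease, "sex_class": c.value,
         "cases": t.cases[c], "total": t.totals[c]}
        for t in tables
        for c in t.classes
    ]
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_count_tables(tables: Iterable[CountTable] | Mapping[str, CountTable], path) -> None:
    """Write count tables in the same CSV schema ``read_count_tables`` reads."""
    if isinstance(tables, Mapping):
        tables = tables.values()
    tables_to_frame(tables).to_csv(path, index=False)


def load_cohort_counts() -> dict[str, CountTable]:
    """Load the packaged retrospective-cohort counts (90,090 dogs, 1995-2010).

    Twelve per-disease tables from a published university veterinary
    teaching-hospital cohort: eleven immune-mediated conditions with all four
    sex classes (denominators F=9,133, NF=36,574, M=12,555, NM=31,828) and
    pyometra with the two female classes only.

    Note on the printed population percentages: the pyometra share (0.44%)
    uses the female-only denominator 45,707, all other conditions use the
    full 90,090.
    """
    ref = resources.files("gonadrisk").joinpath("data/cohort_counts.csv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    tables = _tables_from_frame(df, "cohort_counts.csv")
    return {d: tables[d] for d in COHORT_DISEASES}


# ---------------------------------------------------------------------------
# patient records


@dataclass(frozen=True)
class PatientRecord:
    """One dog: sex, neuter history and first confirmed diagnosis dates."""

    id: str
    sex: str  # 'female' | 'male'
    neutered_ever: bool
    neuter_date: dt.date | None = None
    diagnosis_dates: Mapping[str, dt.date] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"record {self.id}: sex must be female/male")
        if self.neuter_date is not None and not self.neutered_ever:
            raise ValidationError(
                f"record {self.id}: neuter_date present but neutered_ever is false"
            )


def classify_status_at_diagnosis(
    record: PatientRecord, disease: str, window_days: int = 150
) -> SexClass:
    """Sex class of a dog *at the time of* its first diagnosis of ``disease``.

    A dog neutered on or before the diagnosis date was neutered when the
    disease was found (NF/NM).  A dog never neutered, or neutered strictly
    after the diagnosis — including within the ``window_days`` reclassification
    allowance and beyond it — was intact at diagnosis (F/M).  ``window_days``
    documents the study rule that dogs neutered within 150 days after an
    initial diagnosis count as intact; with fully dated records every
    post-diagnosis neuter maps to the intact class, so the argument does not
    alter the decision and is retained for interface clarity.
    """
    if disease not in record.diagnosis_dates:
        raise ValidationError(
            f"record {record.id}: no diagnosis date for {disease!r}"
        )
    if not record.neutered_ever:
        return SexClass.for_sex(record.sex, neutered=False)
    if record.neuter_date is None:
        raise AmbiguousNeuterError(
            f"record {record.id}: neutered but neuter date unknown; "
            "status at diagnosis cannot be dated"
        )
    diagnosed = record.diagnosis_dates[disease]
    neutered_at_diagnosis = record.neuter_date <= diagnosed
    return SexClass.for_sex(record.sex, neutered=neutered_at_diagnosis)


def final_sex_class(record: PatientRecord) -> SexClass:
    """Sex class by final recorded status (used for denominator membership)."""
    return SexClass.for_sex(record.sex, record.neutered_ever)


def aggregate_records(records: Sequence[PatientRecord], disease: str) -> CountTable:
    """Build a disease count table from patient records.

    Each dog contributes exactly once: diagnosed dogs are cases in their
    status-at-diagnosis class; undiagnosed dogs enter the denominator of
    their final recorded class.  Classes with an empty denominator are
    dropped from the table.  Classification ambiguities (neutered dog
    without a neuter date among the cases) propagate with the record id.
    """
    if not records:
        raise ValidationError("aggregate_records: empty record collection")
    cases = {c: 0 for c in CLASS_ORDER}
    totals = {c: 0 for c in CLASS_ORDER}
    for rec in records:
        if disease in rec.diagnosis_dates:
            sc = classify_status_at_diagnosis(rec, disease)
            cases[sc] += 1
        else:
            sc = final_sex_class(rec)
        totals[sc] += 1
    keep = [c for c in CLASS_ORDER if totals[c] > 0]
    return CountTable(
        disease,
        {c: cases[c] for c in keep},
        {c: totals[c] for c in keep},
    )


# ---------------------------------------------------------------------------
# patient-record CSV I/O (long format: one row per diagnosis, or one
# diagnosis-free row for undiagnosed dogs)

RECORD_COLUMNS = ("id", "sex", "neutered_ever", "neuter_date", "disease", "diagnosis_date")


def write_patient_records(records: Iterable[PatientRecord], path) -> None:
    rows = []
    for rec in records:
        base = {
            "id": rec.id,
            "sex": rec.sex,
            "neutered_ever": rec.neutered_ever,
            "neuter_date": rec.neuter_date.isoformat() if rec.neuter_date else "",
        }
        if rec.diagnosis_dates:
            for disease, date in sorted(rec.diagnosis_dates.items()):
                rows.append({**base, "disease": disease, "diagnosis_date": date.isoformat()})
        else:
            rows.append({**base, "disease": "", "diagnosis_date": ""})
    pd.DataFrame(rows, columns=list(RECORD_COLUMNS)).to_csv(path, index=False)


def read_patient_records(path) -> list[PatientRecord]:
    """Read the long-format record CSV written by :func:`write_patient_records`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    records: list[PatientRecord] = []
    for rec_id, group in df.groupby("id", sort=False):
        first = group.iloc[0]
        for col in ("sex", "neutered_ever", "neuter_date"):
            if group[col].nunique() > 1:
                raise ValidationError(f"{path}: record {rec_id}: inconsistent {col}")
        neutered = str(first["neutered_ever"]).strip().lower() in ("true", "1", "yes")
        neuter_date = (
            dt.date.fromisoformat(first["neuter_date"]) if first["neuter_date"] else None
        )
        diagnoses: dict[str, dt.date] = {}
        for row in group.itertuples():
            if row.disease:
                if row.disease in diagnoses:
                    raise ValidationError(
                        f"{path}: record {rec_id}: duplicate diagnosis of {row.disease}"
                    )
                diagnoses[row.disease] = dt.date.fromisoformat(row.diagnosis_date)
        records.append(
            PatientRecord(
                id=str(rec_id),
                sex=str(first["sex"]),
                neutered_ever=neutered,
                neuter_date=neuter_date,
                diagnosis_dates=diagnoses,
            )
        )
    return records
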