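"""Core domain types for OMOP-lite tabular extracts.

The pipeline works on five tables borrowed from the OMOP common data
model, reduced to the columns the sex-incongruence analysis needs:

* ``person`` — survey sex at birth and gender identity,
* ``condition_occurrence`` — one row per EHR condition record,
* ``concept`` — OMOP concept id → human-readable name,
* ``genomic_sex`` (optional) — genotyping-inferred biological sex,
* ``zip3`` (optional) — first three zip-code digits per participant.

Tables live in a :class:`Dataset` as pandas DataFrames with fixed column
order.  Small frozen dataclasses (:class:`Person`, …) are provided for
building datasets record-by-record in tests and examples.
"""
from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

import pandas as pd


class Sex(str, enum.Enum):
    """Survey-reported sex at birth."""

    FEMALE = "female"
    MALE = "male"
    OTHER_OR_UNKNOWN = "other_or_unknown"


class GenderIdentity(str, enum.Enum):
    """Survey-reported gender identity."""

    WOMAN = "woman"
    MAN = "man"
    TRANSGENDER = "transgender"
    NONBINARY = "nonbinary"
    OTHER = "other"
    SKIP = "skip"
    PREFER_NOT_TO_ANSWER = "prefer_not_to_answer"


class GenomicSex(str, enum.Enum):
    """Biological sex inferred from genotyping-array calls."""

    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


#: the two sexes retained by the primary analysis
BINARY_SEXES = (Sex.FEMALE.value, Sex.MALE.value)

#: gender identity that conforms to each binary sex at birth
CIS_GENDER = {
    Sex.FEMALE.value: GenderIdentity.WOMAN.value,
    Sex.MALE.value: GenderIdentity.MAN.value,
}

PERSON_COLUMNS = ["person_id", "sex_at_birth", "gender_identity"]
OCCURRENCE_COLUMNS = ["person_id", "concept_id", "start_date"]
CONCEPT_COLUMNS = ["concept_id", "concept_name"]
GENOMIC_SEX_COLUMNS = ["person_id", "inferred_sex"]
ZIP3_COLUMNS = ["person_id", "zip3"]

_ZIP3_RE = re.compile(r"^\d{3}$")


class DataModelError(ValueError):
    """Invalid or internally inconsistent OMOP-lite data."""


class MissingTableError(DataModelError):
    """A required (or explicitly requested optional) table is absent."""


# ---------------------------------------------------------------------------
# record dataclasses — convenience constructors for small datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Person:
    person_id: str
    sex_at_birth: str = Sex.OTHER_OR_UNKNOWN.value
    gender_identity: str = GenderIdentity.OTHER.value


@dataclass(frozen=True)
class ConditionOccurrence:
    person_id: str
    concept_id: int
    start_date: str | date = "2020-01-01"


@dataclass(frozen=True)
class Concept:
    concept_id: int
    concept_name: str


@dataclass(frozen=True)
class GenomicSexRecord:
    person_id: str
    inferred_sex: str


@dataclass(frozen=True)
class Zip3Record:
    person_id: str
    zip3: str


def _frame(records: Iterable | pd.DataFrame | None, columns: Sequence[str]) -> pd.DataFrame:
    if records is None:
        return pd.DataFrame(columns=list(columns))
    if isinstance(records, pd.DataFrame):
        return records.loc[:, list(columns)].copy()
    rows = [[getattr(r, c) for c in columns] for r in records]
    return pd.DataFrame(rows, columns=list(columns))


def _sorted(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df.reset_index(drop=True)
    return df.sort_values(list(df.columns), kind="mergesort").reset_index(drop=True)


@dataclass
class Dataset:
    """An in-memory OMOP-lite extract.

    ``persons``, ``occurrences`` and ``concepts`` are always present
    (possibly empty); ``genomic_sex`` and ``zip3`` are ``None`` when the
    side table was not provided.
    """

    persons: pd.DataFrame
    occurrences: pd.DataFrame
    concepts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=CONCEPT_COLUMNS)
    )
    genomic_sex: pd.DataFrame | None = None
    zip3: pd.DataFrame | None = None

    # -- construction -------------------------------------------------
    @classmethod
    def empty(cls) -> "Dataset":
        return cls.from_records(persons=[], occurrences=[])

    @classmethod
    def from_records(
        cls,
        persons: Iterable[Person] | pd.DataFrame,
        occurrences: Iterable[ConditionOccurrence] | pd.DataFrame,
        concepts: Iterable[Concept] | pd.DataFrame | None = None,
        genomic_sex: Iterable[GenomicSexRecord] | pd.DataFrame | None = None,
        zip3: Iterable[Zip3Record] | pd.DataFrame | None = None,
    ) -> "Dataset":
        ds = cls(
            persons=_frame(persons, PERSON_COLUMNS),
            occurrences=_frame(occurrences, OCCURRENCE_COLUMNS),
            concepts=_frame(concepts, CONCEPT_COLUMNS),
            genomic_sex=None if genomic_sex is None else _frame(genomic_sex, GENOMIC_SEX_COLUMNS),
            zip3=None if zip3 is None else _frame(zip3, ZIP3_COLUMNS),
        )
        ds._normalize()
        return ds

    def _normalize(self) -> None:
        self.persons = self.persons.astype(
            {"person_id": str, "sex_at_birth": str, "gender_identity": str}
        )
        occ = self.occurrences
        occ = occ.astype({"person_id": str})
        occ["concept_id"] = pd.to_numeric(occ["concept_id"]).astype("int64")
        occ["start_date"] = pd.to_datetime(occ["start_date"])
        self.occurrences = occ
        con = self.concepts
        con["concept_id"] = pd.to_numeric(con["concept_id"]).astype("int64")
        con = con.astype({"concept_name": str})
        self.concepts = con
        if self.genomic_sex is not None:
            self.genomic_sex = self.genomic_sex.astype({"person_id": str, "inferred_sex": str})
        if self.zip3 is not None:
            self.zip3 = self.zip3.astype({"person_id": str, "zip3": str})

    # -- validation ---------------------------------------------------
    def validate(self, strict: bool = True) -> list[str]:
        """Check invariants; returns warnings for non-fatal repairs.

        Fatal problems (duplicate or empty person ids, non-positive
        concept ids, malformed zip3, duplicated genomic-sex rows) raise
        :class:`DataModelError`.  Occurrences referencing an absent
        person are fatal when ``strict`` is on, otherwise dropped in
        place with a warning so that rows-in equals records-out plus
        logged drops.
        """
        warnings: list[str] = []
        pid = self.persons["person_id"]
        if (pid.str.len() == 0).any():
            raise DataModelError("empty person_id in person table")
        if pid.duplicated().any():
            dups = sorted(pid[pid.duplicated()].unique())
            raise DataModelError(f"duplicate person_id(s): {dups[:5]}")
        if (self.occurrences["concept_id"] <= 0).any():
            raise DataModelError("condition_occurrence has non-positive concept_id")
        if not self.concepts.empty and self.concepts["concept_id"].duplicated().any():
            raise DataModelError("duplicate concept_id in concept table")
        if self.zip3 is not None and not self.zip3.empty:
            bad = ~self.zip3["zip3"].str.match(_ZIP3_RE)
            if bad.any():
                raise DataModelError(
                    f"malformed zip3 value(s): {sorted(self.zip3.loc[bad, 'zip3'].unique())[:5]}"
                )
        if self.genomic_sex is not None and self.genomic_sex["person_id"].duplicated().any():
            raise DataModelError("more than one genomic_sex record for a person")

        known = set(pid)
        orphan = ~self.occurrences["person_id"].isin(known)
        if orphan.any():
            msg = (
                f"{int(orphan.sum())} condition_occurrence row(s) reference "
                "person_id(s) absent from the person table"
            )
            if strict:
                raise DataModelError(msg)
            warnings.append(msg + "; dropped")
            self.occurrences = self.occurrences.loc[~orphan].reset_index(drop=True)
        for name in ("genomic_sex", "zip3"):
            tab = getattr(self, name)
            if tab is None:
                continue
            orphan = ~tab["person_id"].isin(known)
            if orphan.any():
                msg = f"{int(orphan.sum())} {name} row(s) reference unknown person_id(s)"
                if strict:
                    raise DataModelError(msg)
                warnings.append(msg + "; dropped")
                setattr(self, name, tab.loc[~orphan].reset_index(drop=True))
        return warnings

    # -- comparison ---------------------------------------------------
    def equals(self, other: "Dataset") -> bool:
        """Row-order-insensitive equality of all tables."""
        for name in ("persons", "occurrences", "concepts"):
            if not _sorted(getattr(self, name)).equals(_sorted(getattr(other, name))):
                return False
        for name in ("genomic_sex", "zip3"):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not _sorted(a).equals(_sorted(b)):
                return False
        return True

    @property
    def n_persons(self) -> int:
        return len(self.persons)
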