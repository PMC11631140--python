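"""CSV readers/writers for the OMOP-lite exchange dialect.

Files are UTF-8 comma-separated with a mandatory header row; string
fields are quoted on output.  Enumerated columns are written as
lowercase snake-case tokens; the loader additionally accepts the survey
literals used by the All of Us questionnaires ("Male", "Female", "Man",
"Woman", "Skip", "PreferNotToAnswer") case-insensitively.  Dates are
ISO 8601 (``YYYY-MM-DD``).
"""
from __future__ import annotations

import csv
import logging
from pathlib import Path

import pandas as pd

from .types import (
    CONCEPT_COLUMNS,
    GENOMIC_SEX_COLUMNS,
    OCCURRENCE_COLUMNS,
    PERSON_COLUMNS,
    ZIP3_COLUMNS,
    DataModelError,
    Dataset,
    GenderIdentity,
    GenomicSex,
    MissingTableError,
    Sex,
)

log = logging.getLogger(__name__)

PERSON_FILE = "person.csv"
OCCURRENCE_FILE = "condition_occurrence.csv"
CONCEPT_FILE = "concept.csv"
GENOMIC_SEX_FILE = "genomic_sex.csv"
ZIP3_FILE = "zip3.csv"


def _alias_map(enum_cls, extra: dict[str, str]) -> dict[str, str]:
    mapping = {m.value.casefold(): m.value for m in enum_cls}
    mapping.update({k.casefold(): v for k, v in extra.items()})
    return mapping

_SEX_MAP = _alias_map(Sex, {"Male": "male", "Female": "female"})
_GENDER_MAP = _alias_map(
    GenderIdentity,
    {
        "Man": "man",
        "Woman": "woman",
        "Skip": "skip",
        "PreferNotToAnswer": "prefer_not_to_answer",
        "non-binary": "nonbinary",
        "non_binary": "nonbinary",
    },
)
_GENOMIC_MAP = _alias_map(GenomicSex, {"Male": "male", "Female": "female"})


def _map_enum(
    series: pd.Series,
    mapping: dict[str, str],
    fallback: str,
    strict: bool,
    where: str,
) -> pd.Series:
    tokens = series.astype(str).str.strip()
    mapped = tokens.str.casefold().map(mapping)
    unknown = mapped.isna() & tokens.notna()
    if unknown.any():
        bad = sorted(tokens[unknown].unique())
        if strict:
            raise DataModelError(f"unrecognized {where} value(s): {bad[:5]}")
        log.warning("mapping %d unrecognized %s value(s) %s to %r",
                    int(unknown.sum()), where, bad[:5], fallback)
        mapped = mapped.where(~unknown, fallback)
    return mapped


def _read(path: Path, columns: list[str], **kwargs) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **kwargs)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataModelError(f"{path.name}: missing column(s) {missing}")
    return df.loc[:, columns]


def load_dataset(directory_path: str | Path, strict: bool = True) -> Dataset:
    """Load an OMOP-lite directory into a validated :class:`Dataset`.

    ``person.csv`` and ``condition_occurrence.csv`` are required;
    ``concept.csv``, ``genomic_sex.csv`` and ``zip3.csv`` are optional.
    With ``strict`` off, unknown enum tokens fall back to
    ``other_or_unknown``/``other``/``unknown`` and occurrences that
    reference absent persons are dropped, both with logged warnings.
    """
    root = Path(directory_path)
    for required in (PERSON_FILE, OCCURRENCE_FILE):
        if not (root / required).is_file():
            raise MissingTableError(f"required file not found: {root / required}")

    persons = _read(root / PERSON_FILE, PERSON_COLUMNS)
    persons["sex_at_birth"] = _map_enum(
        persons["sex_at_birth"], _SEX_MAP, Sex.OTHER_OR_UNKNOWN.value, strict, "sex_at_birth"
    )
    persons["gender_identity"] = _map_enum(
        persons["gender_identity"], _GENDER_MAP, GenderIdentity.OTHER.value,
        strict, "gender_identity",
    )

    occurrences = _read(root / OCCURRENCE_FILE, OCCURRENCE_COLUMNS)
    try:
        occurrences["concept_id"] = pd.to_numeric(occurrences["concept_id"]).astype("int64")
        occurrences["start_date"] = pd.to_datetime(occurrences["start_date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise DataModelError(f"{OCCURRENCE_FILE}: {exc}") from exc

    concepts = None
    if (root / CONCEPT_FILE).is_file():
        concepts = _read(root / CONCEPT_FILE, CONCEPT_COLUMNS)
    genomic = None
    if (root / GENOMIC_SEX_FILE).is_file():
        genomic = _read(root / GENOMIC_SEX_FILE, GENOMIC_SEX_COLUMNS)
        genomic["inferred_sex"] = _map_enum(
            genomic["inferred_sex"], _GENOMIC_MAP, GenomicSex.UNKNOWN.value,
            strict, "inferred_sex",
        )
    zip3 = None
    if (root / ZIP3_FILE).is_file():
        zip3 = _read(root / ZIP3_FILE, ZIP3_COLUMNS)

    ds = Dataset.from_records(
        persons=persons, occurrences=occurrences, concepts=concepts,
        genomic_sex=genomic, zip3=zip3,
    )
    for warning in ds.validate(strict=strict):
        log.warning("%s: %s", root, warning)
    return ds


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, quoting=csv.QUOTE_NONNUMERIC)


def write_dataset(dataset: Dataset, directory_path: str | Path) -> None:
    """Write the dataset as the same CSV files :func:`load_dataset` reads."""
    root = Path(directory_path)
    root.mkdir(parents=True, exist_ok=True)
    _write(dataset.persons, root / PERSON_FILE)
    occ = dataset.occurrences.copy()
    occ["start_date"] = occ["start_date"].dt.strftime("%Y-%m-%d")
    _write(occ, root / OCCURRENCE_FILE)
    _write(dataset.concepts, root / CONCEPT_FILE)
    if dataset.genomic_sex is not None:
        _write(dataset.genomic_sex, root / GENOMIC_SEX_FILE)
    if dataset.zip3 is not None:
        _write(dataset.zip3, root / ZIP3_FILE)
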