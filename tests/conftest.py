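from __future__ import annotations

import pytest

from sexcheck import (
    CohortPolicy,
    ConditionSpec,
    Dataset,
    SexSpecificCondition,
    SyntheticConfig,
    generate_cohort,
    restrict_to_ehr,
    select_cohort,
)
from sexcheck.types import (
    Concept,
    ConditionOccurrence,
    GenomicSexRecord,
    Person,
    Zip3Record,
)

# a small catalogue with enough incongruence to exercise every statistic
ORACLE_CATALOGUE = [
    ConditionSpec(concept_id=11, concept_name="Female condition A",
                  sex_target="female_only", prevalence=0.30),
    ConditionSpec(concept_id=12, concept_name="Female condition B",
                  sex_target="female_only", prevalence=0.20),
    ConditionSpec(concept_id=21, concept_name="Male condition A",
                  sex_target="male_only", prevalence=0.30),
    ConditionSpec(concept_id=22, concept_name="Male condition B",
                  sex_target="male_only", prevalence=0.20),
    ConditionSpec(concept_id=31, concept_name="Neutral condition",
                  sex_target="neutral", prevalence=0.25),
]

ORACLE_CONDITIONS = [
    SexSpecificCondition(11, "Female condition A", "female"),
    SexSpecificCondition(12, "Female condition B", "female"),
    SexSpecificCondition(21, "Male condition A", "male"),
    SexSpecificCondition(22, "Male condition B", "male"),
]


def oracle_config(seed: int, n_persons: int = 400, **overrides) -> SyntheticConfig:
    """A <=1000-person fixture with a high injected error rate."""
    params = dict(
        n_persons=n_persons,
        female_fraction=0.5,
        condition_catalogue=ORACLE_CATALOGUE,
        error_rate=0.10,
        records_per_carrier=2.0,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def cis_cohort(dataset: Dataset) -> set[str]:
    return restrict_to_ehr(dataset, select_cohort(dataset, CohortPolicy()))


@pytest.fixture
def small_dataset() -> Dataset:
    return generate_cohort(oracle_config(seed=42))


@pytest.fixture
def small_cohort(small_dataset) -> set[str]:
    return cis_cohort(small_dataset)


def build_dataset(persons, occurrences, concepts=None, genomic_sex=None, zip3=None):
    """Hand-build a dataset from record dataclasses (thin alias)."""
    return Dataset.from_records(
        persons=persons, occurrences=occurrences, concepts=concepts,
        genomic_sex=genomic_sex, zip3=zip3,
    )


# re-exported builders so tests can write fixtures tersely
P = Person
O = ConditionOccurrence
C = Concept
G = GenomicSexRecord
Z = Zip3Record
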