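"""Participant filtering.

Mirrors the standard funnel of sex-based EHR quality checks: restrict
to binary sex at birth, optionally restrict to sex-conforming
(cisgender) gender identity, then keep only participants with at least
one EHR condition record.  Each filter step's remaining count is
tracked so the funnel can be reported.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

from .types import BINARY_SEXES, CIS_GENDER, Dataset

log = logging.getLogger(__name__)


class GenderPolicy(str, enum.Enum):
    #: keep only persons whose gender identity conforms to their sex at
    #: birth (woman↔female, man↔male); gender-diverse answers and
    #: skip / prefer-not-to-answer are all excluded
    CISGENDER_ONLY = "cisgender_only"
    #: keep every binary-sex person regardless of gender identity
    #: (the sensitivity analysis)
    INCLUDE_ALL_BINARY_SEX = "include_all_binary_sex"


@dataclass(frozen=True)
class CohortPolicy:
    require_binary_sex: bool = True
    gender_policy: GenderPolicy = GenderPolicy.CISGENDER_ONLY


def selection_flow(dataset: Dataset, policy: CohortPolicy = CohortPolicy()
                   ) -> tuple[set[str], list[tuple[str, int]]]:
    """Apply the person-level filters, returning (ids, funnel steps)."""
    df = dataset.persons
    steps = [("all_persons", len(df))]
    if policy.require_binary_sex:
        df = df[df["sex_at_birth"].isin(BINARY_SEXES)]
        steps.append(("binary_sex_at_birth", len(df)))
    if policy.gender_policy is GenderPolicy.CISGENDER_ONLY:
        conforming = df["gender_identity"] == df["sex_at_birth"].map(CIS_GENDER)
        df = df[conforming.fillna(False)]
        steps.append(("sex_conforming_gender", len(df)))
    return set(df["person_id"]), steps


def select_cohort(dataset: Dataset, policy: CohortPolicy = CohortPolicy()) -> set[str]:
    """Person ids satisfying the policy; logs the count at each step."""
    ids, steps = selection_flow(dataset, policy)
    for step, remaining in steps:
        log.info("cohort filter %s: %d remaining", step, remaining)
    return ids


def restrict_to_ehr(dataset: Dataset, ids: set[str]) -> set[str]:
    """Subset of ``ids`` with at least one condition occurrence."""
    with_ehr = ids & set(dataset.occurrences["person_id"])
    log.info("cohort filter with_ehr_conditions: %d remaining", len(with_ehr))
    return with_ehr
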