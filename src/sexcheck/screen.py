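"""Data-driven screening of sex-specific conditions.

Candidate conditions are profiled by distinct-participant counts per
sex, then filtered through five stages:

1. minimum participant count (default: keep conditions with ≥20
   distinct participants),
2. single-sex bias (default: strictly more than 95% of participants of
   one sex),
3. name-based exclusions (default: breast/mammary findings, which males
   can also develop),
4. minimum prevalence for reliable rate estimation (default: ≥1000
   participants),
5. an explicit concept-id exclusion list standing in for manual
   clinical review of non-exclusive conditions.

"Occurrence" throughout means *distinct participant with at least one
record*, never record count: a person with five records of a condition
counts once for that condition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .types import BINARY_SEXES, Dataset

log = logging.getLogger(__name__)

COUNT_COLUMNS = ["concept_id", "concept_name", "n_female", "n_male",
                 "n_total", "majority_sex", "majority_fraction"]
SELECTED_COLUMNS = ["concept_id", "concept_name", "specific_sex",
                    "n_female", "n_male", "n_total", "majority_fraction"]


class ScreenConfig(BaseModel):
    """Thresholds of the condition-screening stages."""

    min_condition_participants: int = Field(default=20, gt=0)
    bias_threshold: float = 0.95  # strict: fraction must exceed this
    min_prevalent_participants: int = Field(default=1000, gt=0)
    name_exclusion_patterns: list[str] = Field(
        default_factory=lambda: ["breast", "mammary"]
    )
    manual_exclusion_concept_ids: list[int] = Field(default_factory=list)

    @field_validator("bias_threshold")
    @classmethod
    def _check_bias(cls, v: float) -> float:
        if not 0.5 < v < 1.0:
            raise ValueError("bias_threshold must lie strictly between 0.5 and 1")
        return v


@dataclass(frozen=True)
class SexSpecificCondition:
    """A screened condition with its assigned specific sex."""

    concept_id: int
    concept_name: str
    specific_sex: str  # "female" or "male"


@dataclass
class ScreenResult:
    """Selected conditions plus the per-stage survivor counts."""

    selected: pd.DataFrame  # SELECTED_COLUMNS
    stages: list[tuple[str, int]]

    def conditions(self) -> list[SexSpecificCondition]:
        return [
            SexSpecificCondition(int(r.concept_id), str(r.concept_name), str(r.specific_sex))
            for r in self.selected.itertuples(index=False)
        ]


def count_by_sex(dataset: Dataset, cohort: set[str]) -> pd.DataFrame:
    """Per-condition distinct-participant counts by sex.

    One row per concept appearing in any cohort member's occurrences,
    with ``n_female``/``n_male`` distinct-participant counts, the
    majority sex ("none" on a tie) and the majority fraction
    ``max(n_female, n_male) / n_total``.
    """
    occ = dataset.occurrences
    pairs = occ.loc[occ["person_id"].isin(cohort), ["person_id", "concept_id"]]
    pairs = pairs.drop_duplicates()
    merged = pairs.merge(dataset.persons[["person_id", "sex_at_birth"]], on="person_id")
    if not merged["sex_at_birth"].isin(BINARY_SEXES).all():
        raise ValueError("count_by_sex requires a cohort of binary-sex persons")
    tab = (
        merged.groupby(["concept_id", "sex_at_birth"]).size()
        .unstack(fill_value=0)
        .reindex(columns=list(BINARY_SEXES), fill_value=0)
    )
    counts = pd.DataFrame({
        "concept_id": tab.index.to_numpy(dtype="int64"),
        "n_female": tab["female"].to_numpy(dtype="int64"),
        "n_male": tab["male"].to_numpy(dtype="int64"),
    })
    counts["n_total"] = counts["n_female"] + counts["n_male"]
    counts["majority_sex"] = np.select(
        [counts["n_female"] > counts["n_male"], counts["n_male"] > counts["n_female"]],
        ["female", "male"], default="none",
    )
    counts["majority_fraction"] = (
        counts[["n_female", "n_male"]].max(axis=1) / counts["n_total"]
    )
    names = dataset.concepts.set_index("concept_id")["concept_name"]
    counts["concept_name"] = counts["concept_id"].map(names).fillna("")
    return counts.loc[:, COUNT_COLUMNS].sort_values("concept_id").reset_index(drop=True)


def screen_conditions(
    counts: pd.DataFrame,
    concepts: pd.DataFrame | None = None,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Apply the five screening stages to per-condition sex counts.

    A condition is selected iff it passes every stage; its
    ``specific_sex`` is the majority sex that survived the bias filter.
    Raising any threshold can only shrink the selection.
    """
    config = config or ScreenConfig()
    df = counts.copy()
    if concepts is not None and not concepts.empty:
        names = concepts.set_index("concept_id")["concept_name"]
        refreshed = df["concept_id"].map(names)
        df["concept_name"] = refreshed.fillna(df["concept_name"])

    zero = df["n_total"] == 0
    if zero.any():
        log.warning("skipping %d condition(s) with zero participants", int(zero.sum()))
        df = df.loc[~zero]

    stages = [("candidate_conditions", len(df))]
    df = df[df["n_total"] >= config.min_condition_participants]
    stages.append(("min_participant_filter", len(df)))
    df = df[(df["majority_sex"] != "none")
            & (df["majority_fraction"] > config.bias_threshold)]
    stages.append(("sex_bias_filter", len(df)))
    if config.name_exclusion_patterns:
        lowered = df["concept_name"].str.lower()
        excluded = np.zeros(len(df), dtype=bool)
        for pattern in config.name_exclusion_patterns:
            excluded |= lowered.str.contains(pattern.lower(), regex=False).to_numpy()
        df = df.loc[~excluded]
    stages.append(("name_exclusion", len(df)))
    df = df[df["n_total"] >= config.min_prevalent_participants]
    stages.append(("prevalence_filter", len(df)))
    df = df[~df["concept_id"].isin(config.manual_exclusion_concept_ids)]
    stages.append(("manual_exclusion", len(df)))

    for stage, remaining in stages:
        log.info("screen stage %s: %d conditions remaining", stage, remaining)

    selected = df.assign(specific_sex=df["majority_sex"])
    selected = selected.loc[:, SELECTED_COLUMNS].reset_index(drop=True)
    return ScreenResult(selected=selected, stages=stages)


def conditions_frame(conditions) -> pd.DataFrame:
    """Normalize any conditions argument to a (concept_id, concept_name,
    specific_sex) DataFrame.

    Accepts a DataFrame with those columns (e.g. ``ScreenResult.selected``)
    or an iterable of :class:`SexSpecificCondition`.
    """
    if isinstance(conditions, ScreenResult):
        conditions = conditions.selected
    if isinstance(conditions, pd.DataFrame):
        df = conditions.loc[:, ["concept_id", "concept_name", "specific_sex"]].copy()
    else:
        df = pd.DataFrame(
            [(c.concept_id, c.concept_name, c.specific_sex) for c in conditions],
            columns=["concept_id", "concept_name", "specific_sex"],
        )
    df["concept_id"] = df["concept_id"].astype("int64")
    bad = ~df["specific_sex"].isin(("female", "male"))
    if bad.any():
        raise ValueError("specific_sex must be 'female' or 'male'")
    return df
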