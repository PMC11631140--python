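"""Characterization of participants with incongruent sex-specific conditions.

Given a screened condition list, these operations ask who the flagged
(incongruent) participants are: whether their genomic-inferred sex
agrees with their survey sex at birth, whether they also carry
conditions congruent to their own sex (a mix of accurate and erroneous
records), how many distinct incongruent conditions they accumulate,
whether they cluster geographically (zip3) or temporally (condition
start year), and how the overall rate shifts when non-cisgender
participants are included.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortPolicy, GenderPolicy, restrict_to_ehr, select_cohort
from .metrics import RateEstimate, compute_oir
from .screen import conditions_frame
from .types import BINARY_SEXES, Dataset, GenderIdentity, MissingTableError


@dataclass(frozen=True)
class ConcordanceResult:
    """Genomic-sex agreement among flagged participants."""

    n_flagged: int
    n_retrieved: int  # flagged persons with a usable genomic call
    n_matched: int    # genomic sex equals survey sex at birth
    match_fraction: float | None  # None when nothing was retrieved


@dataclass(frozen=True)
class SexProportion:
    """A per-sex proportion with its explicit numerator/denominator."""

    n_numerator: int
    n_denominator: int

    @property
    def proportion(self) -> float | None:
        if self.n_denominator == 0:
            return None
        return self.n_numerator / self.n_denominator


def _carrier_pairs(dataset: Dataset, cohort: set[str], cond: pd.DataFrame) -> pd.DataFrame:
    """Distinct (person, concept) pairs of listed conditions in the cohort,
    annotated with person sex and the condition's specific sex."""
    occ = dataset.occurrences
    mask = occ["concept_id"].isin(cond["concept_id"]) & occ["person_id"].isin(cohort)
    pairs = occ.loc[mask, ["person_id", "concept_id"]].drop_duplicates()
    pairs = pairs.merge(dataset.persons[["person_id", "sex_at_birth"]], on="person_id")
    pairs = pairs.merge(cond[["concept_id", "specific_sex"]], on="concept_id")
    pairs["incongruent"] = pairs["sex_at_birth"] != pairs["specific_sex"]
    return pairs


def flag_incongruent_persons(
    dataset: Dataset, cohort: set[str], conditions
) -> dict[str, set[int]]:
    """Map each incongruent person to their incongruent concept ids.

    A person is flagged iff they carry at least one listed condition
    whose specific sex differs from their sex at birth.
    """
    cond = conditions_frame(conditions)
    pairs = _carrier_pairs(dataset, cohort, cond)
    inc = pairs.loc[pairs["incongruent"]]
    return {
        pid: set(int(c) for c in grp)
        for pid, grp in inc.groupby("person_id")["concept_id"]
    }


def genomic_concordance(dataset: Dataset, flagged: dict[str, set[int]]) -> ConcordanceResult:
    """Compare survey sex at birth with genomic-inferred sex for flagged persons.

    Retrieval means a genomic record exists with a determinate
    (female/male) call; an ``unknown`` call counts as not retrieved.
    """
    if dataset.genomic_sex is None:
        raise MissingTableError(
            "genomic_sex table not available; cannot assess concordance"
        )
    ids = pd.Index(sorted(flagged))
    gen = dataset.genomic_sex.set_index("person_id")["inferred_sex"]
    retrieved = gen.reindex(ids).dropna()
    retrieved = retrieved[retrieved.isin(BINARY_SEXES)]
    sex = dataset.persons.set_index("person_id")["sex_at_birth"]
    n_matched = int((retrieved == sex.reindex(retrieved.index)).sum())
    n_retrieved = len(retrieved)
    return ConcordanceResult(
        n_flagged=len(ids),
        n_retrieved=n_retrieved,
        n_matched=n_matched,
        match_fraction=None if n_retrieved == 0 else n_matched / n_retrieved,
    )


def concurrence_rates(
    dataset: Dataset, cohort: set[str], conditions
) -> dict[str, SexProportion]:
    """Per-sex fraction of flagged persons who also carry a condition
    congruent to their own sex (membership in the screened list only)."""
    cond = conditions_frame(conditions)
    if set(cond["specific_sex"]) != {"female", "male"}:
        raise ValueError("concurrence requires both sexes' condition sets")
    pairs = _carrier_pairs(dataset, cohort, cond)
    per_person = pairs.groupby(["person_id", "sex_at_birth"])["incongruent"].agg(["any", "all"])
    flagged = per_person[per_person["any"]]
    result = {}
    for sex in BINARY_SEXES:
        if sex in flagged.index.get_level_values("sex_at_birth"):
            sub = flagged.xs(sex, level="sex_at_birth")
        else:
            sub = pd.DataFrame(columns=["any", "all"])
        # "not all incongruent" == also carries a congruent listed condition
        result[sex] = SexProportion(int((~sub["all"].astype(bool)).sum()), len(sub))
    return result


def multiplicity_rates(
    dataset: Dataset, cohort: set[str], conditions
) -> dict[str, dict[str, SexProportion]]:
    """Per-sex, per-class fraction of persons carrying more than one
    distinct sex-specific condition of the same congruence class.

    The denominator for class *c* and sex *s* is persons of sex *s* with
    at least one class-*c* condition; the numerator requires at least
    two distinct concepts of that class.
    """
    cond = conditions_frame(conditions)
    pairs = _carrier_pairs(dataset, cohort, cond)
    out: dict[str, dict[str, SexProportion]] = {}
    for klass, flag in (("incongruent", True), ("congruent", False)):
        sub = pairs[pairs["incongruent"] == flag]
        n_distinct = sub.groupby(["person_id", "sex_at_birth"])["concept_id"].nunique()
        by_sex: dict[str, SexProportion] = {}
        for sex in BINARY_SEXES:
            counts = (
                n_distinct.xs(sex, level="sex_at_birth")
                if sex in n_distinct.index.get_level_values("sex_at_birth")
                else pd.Series(dtype="int64")
            )
            by_sex[sex] = SexProportion(int((counts > 1).sum()), len(counts))
        out[klass] = by_sex
    return out


def geographic_profile(
    dataset: Dataset, cohort: set[str], flagged: dict[str, set[int]]
) -> tuple[pd.DataFrame, dict]:
    """Zip3-level comparison of population and incongruent-person shares.

    Returns one row per zip3 with at least one cohort member carrying a
    zip3 record: the zip3's share of the profiled population and its
    share of all flagged persons (each column sums to 1).  The summary
    reports how many zip3s contain flagged persons, the Pearson
    correlation between the two share columns over those zip3s, and
    quantile summaries of zip3 population sizes with versus without
    flagged persons.
    """
    if dataset.zip3 is None:
        raise MissingTableError("zip3 table not available; cannot profile geography")
    z = dataset.zip3
    z = z[z["person_id"].isin(cohort)]
    pop = z.groupby("zip3")["person_id"].nunique().rename("n_persons")
    inc = (
        z[z["person_id"].isin(flagged)]
        .groupby("zip3")["person_id"].nunique()
        .reindex(pop.index, fill_value=0)
        .rename("n_incongruent")
    )
    rows = pd.DataFrame({"zip3": pop.index, "n_persons": pop.to_numpy(),
                         "n_incongruent": inc.to_numpy()})
    total_pop = rows["n_persons"].sum()
    total_inc = rows["n_incongruent"].sum()
    rows["population_fraction"] = rows["n_persons"] / total_pop if total_pop else 0.0
    rows["incongruent_fraction"] = (
        rows["n_incongruent"] / total_inc if total_inc else 0.0
    )
    rows = rows.sort_values("zip3").reset_index(drop=True)

    with_flagged = rows[rows["n_incongruent"] > 0]
    without_flagged = rows[rows["n_incongruent"] == 0]
    if len(with_flagged) >= 2 and with_flagged["population_fraction"].nunique() > 1:
        r = float(stats.pearsonr(with_flagged["population_fraction"],
                                 with_flagged["incongruent_fraction"])[0])
    else:
        r = None

    def quantiles(series: pd.Series) -> dict[str, float] | None:
        if series.empty:
            return None
        qs = series.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
        return {"min": float(qs.iloc[0]), "q25": float(qs.iloc[1]),
                "median": float(qs.iloc[2]), "q75": float(qs.iloc[3]),
                "max": float(qs.iloc[4])}

    summary = {
        "n_zip3_total": len(rows),
        "n_zip3_with_flagged": len(with_flagged),
        "pearson_r": r,
        "population_with_flagged": quantiles(with_flagged["n_persons"]),
        "population_without_flagged": quantiles(without_flagged["n_persons"]),
    }
    return rows, summary


def temporal_profile(dataset: Dataset, cohort: set[str], conditions) -> pd.DataFrame:
    """Condition-record counts by start year, condition sex-specificity
    and the congruence class of the record's person.

    Counts records (not persons): a person contributes every dated
    record of a listed condition.  A person's class is ``incongruent``
    if they carry at least one incongruent listed condition, else
    ``congruent``.
    """
    cond = conditions_frame(conditions)
    columns = ["year", "sex_specificity", "congruence_class", "n_records"]
    if cond.empty:
        return pd.DataFrame(columns=columns)
    flagged = flag_incongruent_persons(dataset, cohort, cond)
    occ = dataset.occurrences
    mask = occ["concept_id"].isin(cond["concept_id"]) & occ["person_id"].isin(cohort)
    recs = occ.loc[mask, ["person_id", "concept_id", "start_date"]].copy()
    if recs.empty:
        return pd.DataFrame(columns=columns)
    recs["year"] = recs["start_date"].dt.year
    specificity = cond.set_index("concept_id")["specific_sex"] + "_specific"
    recs["sex_specificity"] = recs["concept_id"].map(specificity)
    recs["congruence_class"] = np.where(
        recs["person_id"].isin(flagged), "incongruent", "congruent"
    )
    out = (
        recs.groupby(["year", "sex_specificity", "congruence_class"])
        .size().rename("n_records").reset_index()
    )
    return out.sort_values(columns[:3]).reset_index(drop=True)


_NON_ANSWERS = (GenderIdentity.SKIP.value, GenderIdentity.PREFER_NOT_TO_ANSWER.value)


def sensitivity_noncisgender(
    dataset: Dataset, conditions, z: float = 1.96
) -> tuple[RateEstimate, pd.DataFrame]:
    """Recompute the combined OIR with non-cisgender participants included.

    The cohort keeps every binary-sex person regardless of gender
    identity.  The accompanying composition table gives gender-identity
    fractions among all binary-sex participants and among flagged
    participants, with skip / prefer-not-to-answer responses removed
    before fractions are taken.
    """
    cond = conditions_frame(conditions)
    policy = CohortPolicy(gender_policy=GenderPolicy.INCLUDE_ALL_BINARY_SEX)
    cohort = restrict_to_ehr(dataset, select_cohort(dataset, policy))
    estimate = compute_oir(dataset, cohort, cond, "combined", z)
    flagged = flag_incongruent_persons(dataset, cohort, cond)

    persons = dataset.persons
    binary = persons[persons["sex_at_birth"].isin(BINARY_SEXES)]
    answered = binary[~binary["gender_identity"].isin(_NON_ANSWERS)]
    flagged_answered = answered[answered["person_id"].isin(flagged)]

    def fractions(df: pd.DataFrame) -> pd.Series:
        if df.empty:
            return pd.Series(dtype=float)
        return df["gender_identity"].value_counts(normalize=True)

    all_frac = fractions(answered)
    flag_frac = fractions(flagged_answered)
    categories = sorted(set(all_frac.index) | set(flag_frac.index))
    composition = pd.DataFrame({
        "gender_identity": categories,
        "fraction_all": [float(all_frac.get(c, 0.0)) for c in categories],
        "fraction_flagged": [float(flag_frac.get(c, 0.0)) for c in categories],
    })
    return estimate, composition
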