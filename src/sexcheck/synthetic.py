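"""Synthetic OMOP-lite cohort generator.

Emulates the statistical structure the incongruence-rate analysis
assumes: a two-sex adult cohort with a configurable gender-identity mix
(mostly cisgender, with small transgender / nonbinary / other / skip
fractions), a condition catalogue mixing sex-specific and sex-neutral
conditions with per-condition prevalence, and an injected logging-error
rate ``error_rate`` (ε) that mis-assigns condition records across sexes.

The default error model is *record-level mis-assignment*: each record of
a sex-specific condition is, with probability ε, attached to a uniformly
chosen person of the opposite sex instead of its carrier.  This
reproduces the signature seen in real EHR audits — incongruent
participants retain a mix of accurate and erroneous records — which a
person-level sex swap would not.  A ``person_swap`` mode (the carrier's
whole record set for a condition moves to one opposite-sex person) is
available for contrast experiments.

:func:`expected_oir` gives the analytic expectation of the person-level
overall incongruence rate implied by a configuration, used as the target
of parameter-recovery checks.
"""
from __future__ import annotations

import math
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .types import (
    CONCEPT_COLUMNS,
    GENOMIC_SEX_COLUMNS,
    OCCURRENCE_COLUMNS,
    PERSON_COLUMNS,
    ZIP3_COLUMNS,
    CIS_GENDER,
    Dataset,
)

SexTarget = Literal["female_only", "male_only", "neutral"]


class ConditionSpec(BaseModel):
    """One catalogue entry: a condition with a target sex and prevalence.

    ``prevalence`` is the probability that a member of the target sex
    (or of anyone, for neutral conditions) carries the condition.
    """

    concept_id: int = Field(gt=0)
    concept_name: str
    sex_target: SexTarget
    prevalence: float = Field(ge=0.0, le=1.0)


def _default_gender_distribution() -> dict[str, dict[str, float]]:
    # ~96% cisgender per sex; gender-diverse and non-answer fractions of
    # the order seen in large US research cohorts (All of Us reports
    # 1.11% with gender differing from sex at birth).
    return {
        "female": {
            "woman": 0.961, "man": 0.003, "transgender": 0.004,
            "nonbinary": 0.006, "other": 0.002, "skip": 0.012,
            "prefer_not_to_answer": 0.012,
        },
        "male": {
            "man": 0.961, "woman": 0.003, "transgender": 0.004,
            "nonbinary": 0.006, "other": 0.002, "skip": 0.012,
            "prefer_not_to_answer": 0.012,
        },
    }


def default_condition_catalogue() -> list[ConditionSpec]:
    """A small catalogue spanning the screening regimes.

    Mixes prevalent female-specific and male-specific conditions (OMOP
    ids of well-known sex-specific concepts), sex-neutral chronic
    conditions, one rare sex-specific condition (exercises the
    minimum-participant cut) and one breast finding (exercises the
    name-based exclusion).
    """
    rows = [
        (4299535, "Finding related to pregnancy", "female_only", 0.150),
        (4129155, "Ovarian cyst", "female_only", 0.050),
        (201909, "Female infertility", "female_only", 0.025),
        (4279913, "Primary ovarian failure", "female_only", 0.024),
        (440787, "Drug dependence in mother complicating pregnancy", "female_only", 0.007),
        (200962, "Primary malignant neoplasm of prostate", "male_only", 0.060),
        (26662, "Testicular hypofunction", "male_only", 0.045),
        (197605, "Inflammatory disorder of male genital organ", "male_only", 0.015),
        (4112853, "Benign neoplasm of breast", "female_only", 0.040),
        (4095940, "Rare disorder of uterus", "female_only", 0.0004),
        (320128, "Essential hypertension", "neutral", 0.300),
        (201826, "Type 2 diabetes mellitus", "neutral", 0.120),
        (317009, "Asthma", "neutral", 0.100),
    ]
    return [
        ConditionSpec(concept_id=i, concept_name=n, sex_target=t, prevalence=p)
        for i, n, t, p in rows
    ]


def _default_zip3_weights() -> dict[str, float]:
    # heterogeneous metro-like population weights over 20 zip3 areas
    zips = ["100", "112", "191", "300", "331", "441", "452", "481", "600",
            "606", "630", "750", "752", "770", "787", "802", "850", "900",
            "941", "980"]
    weights = [9, 7, 6, 5, 4, 3, 3, 3, 8, 6, 2, 5, 4, 6, 3, 2, 3, 9, 4, 3]
    return dict(zip(zips, (float(w) for w in weights)))


class SyntheticConfig(BaseModel):
    """Full parameterization of one synthetic cohort."""

    n_persons: int = Field(default=5000, ge=0)
    female_fraction: float = Field(default=0.62, ge=0.0, le=1.0)
    gender_identity_distribution: dict[str, dict[str, float]] = Field(
        default_factory=_default_gender_distribution
    )
    condition_catalogue: list[ConditionSpec] = Field(
        default_factory=default_condition_catalogue
    )
    error_rate: float = Field(default=0.01, ge=0.0, le=1.0)
    error_mode: Literal["record_misassignment", "person_swap"] = "record_misassignment"
    genomic_mismatch_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    genomic_coverage: float = Field(default=1.0, ge=0.0, le=1.0)
    zip3_weights: dict[str, float] = Field(default_factory=_default_zip3_weights)
    year_range: tuple[int, int] = (2000, 2022)
    records_per_carrier: float = Field(default=3.0, ge=1.0)
    seed: int = 0

    @field_validator("gender_identity_distribution")
    @classmethod
    def _check_distribution(cls, v):
        for sex in ("female", "male"):
            if sex not in v:
                raise ValueError(f"gender_identity_distribution missing key {sex!r}")
            total = sum(v[sex].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"gender probabilities for {sex!r} sum to {total!r}, not 1"
                )
            if any(p < 0 for p in v[sex].values()):
                raise ValueError("negative gender probability")
        return v

    @field_validator("zip3_weights")
    @classmethod
    def _check_zip3(cls, v):
        if not v:
            raise ValueError("zip3_weights must be nonempty")
        for z, w in v.items():
            if len(z) != 3 or not z.isdigit():
                raise ValueError(f"zip3 key {z!r} is not 3 digits")
            if w <= 0:
                raise ValueError(f"zip3 weight for {z!r} must be positive")
        return v

    @model_validator(mode="after")
    def _check_years(self):
        y0, y1 = self.year_range
        if y0 > y1:
            raise ValueError("year_range must be (first, last) with first <= last")
        return self


def _draw_categorical(rng: np.random.Generator, categories: list[str],
                      probs: list[float], size: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(categories), size=size, p=p)
    return np.asarray(categories, dtype=object)[idx]


def generate_cohort(config: SyntheticConfig) -> Dataset:
    """Generate a deterministic synthetic :class:`Dataset`.

    The same configuration (including seed) always yields a
    bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    ids = np.array([f"P{i:07d}" for i in range(n)], dtype=object)
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male").astype(object)

    gender = np.empty(n, dtype=object)
    for s in ("female", "male"):
        idx = np.flatnonzero(sex == s)
        dist = config.gender_identity_distribution[s]
        cats = sorted(dist)  # sorted: independent of dict insertion order
        gender[idx] = _draw_categorical(rng, cats, [dist[c] for c in cats], len(idx))

    fem_idx = np.flatnonzero(sex == "female")
    male_idx = np.flatnonzero(sex == "male")
    pools = {"female_only": fem_idx, "male_only": male_idx,
             "neutral": np.arange(n)}
    opposite = {"female_only": male_idx, "male_only": fem_idx}

    rec_person: list[np.ndarray] = []
    rec_concept: list[np.ndarray] = []
    rec_year: list[np.ndarray] = []
    rec_doy: list[np.ndarray] = []
    y0, y1 = config.year_range
    for spec in config.condition_catalogue:
        pool = pools[spec.sex_target]
        carriers = pool[rng.random(len(pool)) < spec.prevalence]
        k = 1 + rng.poisson(config.records_per_carrier - 1.0, size=len(carriers))
        owner = np.repeat(carriers, k)
        if spec.sex_target != "neutral" and config.error_rate > 0:
            targets = opposite[spec.sex_target]
            if len(targets) > 0:
                if config.error_mode == "record_misassignment":
                    flip = rng.random(len(owner)) < config.error_rate
                    owner = owner.copy()
                    owner[flip] = rng.choice(targets, size=int(flip.sum()))
                else:  # person_swap: the carrier's whole record set moves
                    swap = rng.random(len(carriers)) < config.error_rate
                    dest = carriers.copy()
                    dest[swap] = rng.choice(targets, size=int(swap.sum()))
                    owner = np.repeat(dest, k)
        nrec = len(owner)
        rec_person.append(owner)
        rec_concept.append(np.full(nrec, spec.concept_id, dtype="int64"))
        rec_year.append(rng.integers(y0, y1 + 1, size=nrec))
        rec_doy.append(rng.integers(0, 365, size=nrec))

    if rec_person:
        person_idx = np.concatenate(rec_person)
        concept_id = np.concatenate(rec_concept)
        years = np.concatenate(rec_year)
        doys = np.concatenate(rec_doy)
    else:
        person_idx = np.empty(0, dtype="int64")
        concept_id = np.empty(0, dtype="int64")
        years = np.empty(0, dtype="int64")
        doys = np.empty(0, dtype="int64")

    dates = pd.to_datetime(
        pd.DataFrame({"year": years, "month": 1, "day": 1})
    ) + pd.to_timedelta(doys, unit="D")
    occurrences = pd.DataFrame(
        {"person_id": ids[person_idx] if n else np.empty(0, dtype=object),
         "concept_id": concept_id, "start_date": dates},
        columns=OCCURRENCE_COLUMNS,
    )

    persons = pd.DataFrame(
        {"person_id": ids, "sex_at_birth": sex, "gender_identity": gender},
        columns=PERSON_COLUMNS,
    )
    concepts = pd.DataFrame(
        [(s.concept_id, s.concept_name) for s in config.condition_catalogue],
        columns=CONCEPT_COLUMNS,
    )

    # zip3 for every person with at least one condition record
    with_cond = np.unique(person_idx)
    zip_keys = sorted(config.zip3_weights)
    zvals = _draw_categorical(
        rng, zip_keys, [config.zip3_weights[z] for z in zip_keys], len(with_cond)
    )
    zip3 = pd.DataFrame(
        {"person_id": ids[with_cond] if n else np.empty(0, dtype=object), "zip3": zvals},
        columns=ZIP3_COLUMNS,
    )

    # genomic sex: equals sex at birth, flipped with the mismatch rate,
    # reported only for the covered fraction of the cohort
    covered = rng.random(n) < config.genomic_coverage
    flip = rng.random(n) < config.genomic_mismatch_rate
    inferred = sex.copy()
    inferred[flip & (sex == "female")] = "male"
    inferred[flip & (sex == "male")] = "female"
    genomic = pd.DataFrame(
        {"person_id": ids[covered], "inferred_sex": inferred[covered]},
        columns=GENOMIC_SEX_COLUMNS,
    )

    return Dataset.from_records(
        persons=persons, occurrences=occurrences, concepts=concepts,
        genomic_sex=genomic, zip3=zip3,
    )


# ---------------------------------------------------------------------------
# analytic expectation of the overall incongruence rate
# ---------------------------------------------------------------------------

def _record_count_pgf(t: float, mean_records: float) -> float:
    """PGF of the per-carrier record count K = 1 + Poisson(mean-1)."""
    lam = mean_records - 1.0
    return t * math.exp(lam * (t - 1.0))


def expected_oir(
    config: SyntheticConfig,
    gender_policy: str = "cisgender_only",
) -> float:
    """Analytic expectation of the combined person-level OIR.

    Computed as the ratio of expected incongruent to expected total
    distinct-person counts under the generative rules, summing the
    female-specific and male-specific subsets the way the combined OIR
    does.  For the record-mis-assignment model with per-carrier record
    count K (pgf ``g``), a person of the opposite sex escapes condition
    ``c`` (prevalence q, source pool size n_src, target pool size n_tgt)
    with probability ``(1 - q*(1 - g(1 - eps/n_tgt)))**n_src``, and a
    carrier retains at least one of their own records with probability
    ``1 - g(eps)``.  The ``person_swap`` mode replaces these with the
    corresponding whole-set expressions.  Agreement with brute-force
    simulation is part of the test suite.
    """
    fem = [c for c in config.condition_catalogue if c.sex_target == "female_only"]
    mal = [c for c in config.condition_catalogue if c.sex_target == "male_only"]
    if not fem and not mal:
        raise ValueError("expected_oir is undefined for an all-neutral catalogue")

    n = config.n_persons
    n_f = n * config.female_fraction
    n_m = n * (1.0 - config.female_fraction)
    if gender_policy == "cisgender_only":
        c_f = config.gender_identity_distribution["female"].get(CIS_GENDER["female"], 0.0)
        c_m = config.gender_identity_distribution["male"].get(CIS_GENDER["male"], 0.0)
    else:
        c_f = c_m = 1.0
    eps = config.error_rate
    r = config.records_per_carrier
    swap = config.error_mode == "person_swap"

    def subset(specs, n_src, n_tgt, c_src, c_tgt):
        if not specs or n_src <= 0:
            return 0.0, 0.0
        can_misassign = eps > 0 and n_tgt > 0
        p_no_hit = 1.0
        p_no_retain = 1.0
        for s in specs:
            q = s.prevalence
            if can_misassign:
                if swap:
                    hit = eps / n_tgt
                    retain = 1.0 - eps
                else:
                    hit = 1.0 - _record_count_pgf(1.0 - eps / n_tgt, r)
                    retain = 1.0 - _record_count_pgf(eps, r)
            else:
                hit = 0.0
                retain = 1.0
            p_no_hit *= (1.0 - q * hit) ** n_src
            p_no_retain *= 1.0 - q * retain
        e_incongruent = c_tgt * n_tgt * (1.0 - p_no_hit)
        e_congruent = c_src * n_src * (1.0 - p_no_retain)
        return e_incongruent, e_congruent

    ei_f, ec_f = subset(fem, n_f, n_m, c_f, c_m)
    ei_m, ec_m = subset(mal, n_m, n_f, c_m, c_f)
    total = ei_f + ec_f + ei_m + ec_m
    if total == 0.0:
        raise ValueError("expected_oir undefined: no persons expected to carry "
                         "a sex-specific condition under this configuration")
    return (ei_f + ei_m) / total
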