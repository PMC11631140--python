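"""Incongruence-rate statistics.

The condition-specific incongruence rate (CIR) of one sex-specific
condition is

    CIR = N_incongruent / N_total,

where ``N_incongruent`` counts distinct participants carrying the
condition whose sex at birth conflicts with the condition's specific
sex and ``N_total`` counts all distinct participants carrying it.  The
overall incongruence rate (OIR) applies the same person-level ratio to
a collective set of sex-specific conditions; the combined OIR sums the
female-specific and male-specific subset counts, so a person carrying
conditions specific to both sexes contributes to both subsets.

Uncertainty is a Wald (normal-approximation) interval

    p ± z · sqrt(p (1 − p) / n),        z = 1.96 for 95%,

deliberately left unclamped so that small incongruent counts can
produce negative lower bounds, as published reference tables do.  Two
``n`` conventions are provided: ``total`` (the formula's natural n) and
``incongruent`` (n = N_incongruent), the convention that reproduces
the per-condition intervals of the reference study.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .types import Dataset
from .screen import conditions_frame

CiNMode = Literal["total", "incongruent"]

OIR_SUBSETS = ("female_specific", "male_specific", "combined")


class UndefinedRateError(ValueError):
    """A rate was requested for an empty denominator."""


def wald_ci(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wald interval ``p ± z*sqrt(p(1-p)/n)``, unclamped.

    ``p = 0`` (or 1) gives a zero-width interval for any ``n``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion p={p} outside [0, 1]")
    if n < 1:
        raise UndefinedRateError("wald_ci requires n >= 1")
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (p - half, p + half)


@dataclass(frozen=True)
class RateEstimate:
    """An incongruence rate with its interval and provenance counts."""

    label: str
    n_incongruent: int
    n_congruent: int
    n_total: int
    rate: float
    ci_low: float
    ci_high: float
    z: float = 1.96
    ci_n_mode: CiNMode = "total"

    @classmethod
    def from_counts(
        cls,
        label: str,
        n_incongruent: int,
        n_congruent: int,
        z: float = 1.96,
        ci_n_mode: CiNMode = "total",
        clamp: bool = False,
    ) -> "RateEstimate":
        n_total = n_incongruent + n_congruent
        if n_total == 0:
            raise UndefinedRateError(f"{label}: no participants carry the condition(s)")
        rate = n_incongruent / n_total
        n_ci = n_total if ci_n_mode == "total" else n_incongruent
        if n_ci == 0:
            # only reachable in incongruent mode with rate 0
            ci_low = ci_high = rate
        else:
            ci_low, ci_high = wald_ci(rate, n_ci, z)
        if clamp:
            ci_low, ci_high = max(ci_low, 0.0), min(ci_high, 1.0)
        return cls(label, n_incongruent, n_congruent, n_total, rate,
                   ci_low, ci_high, z, ci_n_mode)


def _sex_of_carriers(dataset: Dataset, cohort: set[str], concept_ids) -> pd.Series:
    """Sex at birth of distinct cohort carriers of any listed concept."""
    occ = dataset.occurrences
    mask = occ["concept_id"].isin(concept_ids) & occ["person_id"].isin(cohort)
    carriers = occ.loc[mask, "person_id"].drop_duplicates()
    sex = dataset.persons.set_index("person_id")["sex_at_birth"]
    return carriers.map(sex)


def compute_cir(
    dataset: Dataset,
    cohort: set[str],
    condition,
    z: float = 1.96,
    ci_n_mode: CiNMode = "total",
) -> RateEstimate:
    """Condition-specific incongruence rate for one screened condition.

    ``condition`` is anything with ``concept_id``, ``concept_name`` and
    ``specific_sex`` attributes (a :class:`~sexcheck.screen.SexSpecificCondition`,
    a DataFrame row, …).  Persons are counted once regardless of record
    multiplicity.  An empty denominator raises
    :class:`UndefinedRateError`, never a silent zero.
    """
    specific = str(condition.specific_sex)
    if specific not in ("female", "male"):
        raise ValueError(f"condition has no specific sex: {specific!r}")
    sexes = _sex_of_carriers(dataset, cohort, [int(condition.concept_id)])
    n_congruent = int((sexes == specific).sum())
    n_incongruent = int(len(sexes) - n_congruent)
    return RateEstimate.from_counts(
        str(condition.concept_name), n_incongruent, n_congruent, z, ci_n_mode
    )


def compute_oir(
    dataset: Dataset,
    cohort: set[str],
    conditions,
    sex_subset: str = "combined",
    z: float = 1.96,
) -> RateEstimate:
    """Overall incongruence rate for a collective condition set.

    ``female_specific`` (resp. ``male_specific``) counts distinct
    persons with at least one listed condition of that specificity,
    split into the non-matching (incongruent) and matching (congruent)
    sex.  ``combined`` sums the two subsets' counts.  The interval
    always uses ``n = n_total``.
    """
    if sex_subset not in OIR_SUBSETS:
        raise ValueError(f"sex_subset must be one of {OIR_SUBSETS}")
    cond = conditions_frame(conditions)

    def subset_counts(specific: str) -> tuple[int, int]:
        ids = cond.loc[cond["specific_sex"] == specific, "concept_id"]
        if ids.empty:
            raise UndefinedRateError(f"no {specific}-specific conditions in the set")
        sexes = _sex_of_carriers(dataset, cohort, ids)
        n_congruent = int((sexes == specific).sum())
        return int(len(sexes) - n_congruent), n_congruent

    if sex_subset == "combined":
        inc_f, cong_f = subset_counts("female")
        inc_m, cong_m = subset_counts("male")
        n_inc, n_cong = inc_f + inc_m, cong_f + cong_m
        label = f"{len(cond)} female or male-specific conditions"
    else:
        specific = sex_subset.removesuffix("_specific")
        n_inc, n_cong = subset_counts(specific)
        n_sub = int((cond["specific_sex"] == specific).sum())
        label = f"{n_sub} {specific}-specific conditions"
    return RateEstimate.from_counts(label, n_inc, n_cong, z, ci_n_mode="total")


def mask_small_counts(
    report_table: pd.DataFrame,
    threshold: int = 20,
    count_columns: list[str] | None = None,
    rate_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Small-cell suppression for public report tables.

    Every count strictly below ``threshold`` is replaced by the marker
    ``"<threshold>"`` (e.g. ``"<20"``); derived rate columns are masked
    for any row with a masked count.  By default integer columns are
    treated as counts and float columns as derived rates.
    """
    out = report_table.copy()
    if count_columns is None:
        count_columns = [c for c in out.columns
                         if pd.api.types.is_integer_dtype(out[c])]
    if rate_columns is None:
        rate_columns = [c for c in out.columns
                        if pd.api.types.is_float_dtype(out[c])]
    marker = f"<{threshold}"
    masked_rows = pd.Series(False, index=out.index)
    for col in count_columns:
        cell_masked = out[col] < threshold
        masked_rows |= cell_masked
        out[col] = out[col].astype(object).where(~cell_masked, marker)
    for col in rate_columns:
        out[col] = out[col].astype(object).where(~masked_rows, marker)
    return out
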