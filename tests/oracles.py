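"""Independent brute-force reference implementations.

Pure-Python nested-loop recounts of every statistic the package
computes with vectorized pandas.  Intentionally slow and simple: these
are the oracles the fast implementations are checked against on small
fixtures, so they must not share code with the package.
"""
from __future__ import annotations

import collections


def person_sex(dataset) -> dict[str, str]:
    return dict(zip(dataset.persons["person_id"], dataset.persons["sex_at_birth"]))


def carriers_by_condition(dataset, cohort) -> dict[int, set[str]]:
    """concept_id -> set of distinct cohort carriers."""
    out: dict[int, set[str]] = collections.defaultdict(set)
    for row in dataset.occurrences.itertuples(index=False):
        if row.person_id in cohort:
            out[int(row.concept_id)].add(row.person_id)
    return dict(out)


def brute_restrict_to_ehr(dataset, ids) -> set[str]:
    keep = set()
    for row in dataset.occurrences.itertuples(index=False):
        if row.person_id in ids:
            keep.add(row.person_id)
    return keep


def brute_count_by_sex(dataset, cohort) -> dict[int, tuple[int, int]]:
    """concept_id -> (n_female, n_male) distinct participants."""
    sex = person_sex(dataset)
    carriers = carriers_by_condition(dataset, cohort)
    out = {}
    for concept, people in carriers.items():
        n_f = sum(1 for p in people if sex[p] == "female")
        n_m = sum(1 for p in people if sex[p] == "male")
        out[concept] = (n_f, n_m)
    return out


def brute_cir_counts(dataset, cohort, concept_id, specific_sex) -> tuple[int, int]:
    """(n_incongruent, n_congruent) for one condition."""
    sex = person_sex(dataset)
    people = carriers_by_condition(dataset, cohort).get(int(concept_id), set())
    n_cong = sum(1 for p in people if sex[p] == specific_sex)
    return len(people) - n_cong, n_cong


def _subset_ids(conditions, specific_sex):
    return [c.concept_id for c in conditions if c.specific_sex == specific_sex]


def brute_oir_counts(dataset, cohort, conditions, sex_subset) -> tuple[int, int]:
    """(n_incongruent, n_congruent) with the combined-summation convention."""
    if sex_subset == "combined":
        fi, fc = brute_oir_counts(dataset, cohort, conditions, "female_specific")
        mi, mc = brute_oir_counts(dataset, cohort, conditions, "male_specific")
        return fi + mi, fc + mc
    specific = sex_subset.removesuffix("_specific")
    ids = set(_subset_ids(conditions, specific))
    sex = person_sex(dataset)
    people = set()
    for concept, carriers in carriers_by_condition(dataset, cohort).items():
        if concept in ids:
            people |= carriers
    n_cong = sum(1 for p in people if sex[p] == specific)
    return len(people) - n_cong, n_cong


def brute_flag(dataset, cohort, conditions) -> dict[str, set[int]]:
    sex = person_sex(dataset)
    specific = {c.concept_id: c.specific_sex for c in conditions}
    out: dict[str, set[int]] = collections.defaultdict(set)
    for row in dataset.occurrences.itertuples(index=False):
        concept = int(row.concept_id)
        if row.person_id in cohort and concept in specific:
            if sex[row.person_id] != specific[concept]:
                out[row.person_id].add(concept)
    return dict(out)


def brute_concurrence(dataset, cohort, conditions) -> dict[str, tuple[int, int]]:
    """sex -> (n flagged persons also carrying a congruent condition, n flagged)."""
    sex = person_sex(dataset)
    specific = {c.concept_id: c.specific_sex for c in conditions}
    listed: dict[str, set[int]] = collections.defaultdict(set)
    for row in dataset.occurrences.itertuples(index=False):
        if row.person_id in cohort and int(row.concept_id) in specific:
            listed[row.person_id].add(int(row.concept_id))
    out = {}
    for s in ("female", "male"):
        num = den = 0
        for person, concepts in listed.items():
            if sex[person] != s:
                continue
            has_incongruent = any(specific[c] != s for c in concepts)
            has_congruent = any(specific[c] == s for c in concepts)
            if has_incongruent:
                den += 1
                num += has_congruent
        out[s] = (num, den)
    return out


def brute_multiplicity(dataset, cohort, conditions) -> dict[str, dict[str, tuple[int, int]]]:
    """class -> sex -> (n with >1 distinct same-class condition, n with >=1)."""
    sex = person_sex(dataset)
    specific = {c.concept_id: c.specific_sex for c in conditions}
    listed: dict[str, set[int]] = collections.defaultdict(set)
    for row in dataset.occurrences.itertuples(index=False):
        if row.person_id in cohort and int(row.concept_id) in specific:
            listed[row.person_id].add(int(row.concept_id))
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for klass in ("incongruent", "congruent"):
        out[klass] = {}
        for s in ("female", "male"):
            num = den = 0
            for person, concepts in listed.items():
                if sex[person] != s:
                    continue
                if klass == "incongruent":
                    n_class = sum(1 for c in concepts if specific[c] != s)
                else:
                    n_class = sum(1 for c in concepts if specific[c] == s)
                if n_class >= 1:
                    den += 1
                    num += n_class > 1
            out[klass][s] = (num, den)
    return out


def brute_geography(dataset, cohort, flagged) -> dict[str, tuple[int, int]]:
    """zip3 -> (n cohort persons, n flagged persons) from the zip3 table."""
    out: dict[str, list[set]] = {}
    for row in dataset.zip3.itertuples(index=False):
        if row.person_id not in cohort:
            continue
        bucket = out.setdefault(row.zip3, [set(), set()])
        bucket[0].add(row.person_id)
        if row.person_id in flagged:
            bucket[1].add(row.person_id)
    return {z: (len(pop), len(inc)) for z, (pop, inc) in out.items()}
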