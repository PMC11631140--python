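"""Profiling of incongruent participants: concordance, concurrence,
multiplicity, geography, time, and the non-cisgender sensitivity run."""
from __future__ import annotations

import pytest
from scipy import stats

from conftest import C, G, O, P, Z, build_dataset, ORACLE_CONDITIONS, cis_cohort, oracle_config
from oracles import brute_concurrence, brute_flag, brute_geography, brute_multiplicity
from sexcheck import (
    MissingTableError,
    SexSpecificCondition,
    compute_oir,
    concurrence_rates,
    flag_incongruent_persons,
    generate_cohort,
    genomic_concordance,
    geographic_profile,
    multiplicity_rates,
    sensitivity_noncisgender,
    temporal_profile,
)

FEMALE_COND = SexSpecificCondition(1, "Pregnancy-related finding", "female")
MALE_COND = SexSpecificCondition(2, "Prostate finding", "male")
PAIR = [FEMALE_COND, MALE_COND]


def test_flagging_definition():
    ds = build_dataset(
        [P("m1", "male", "man"), P("m2", "male", "man"), P("f1", "female", "woman")],
        [O("m1", 2), O("m2", 1), O("m2", 1), O("f1", 1)],
    )
    cohort = {"m1", "m2", "f1"}
    flagged = flag_incongruent_persons(ds, cohort, PAIR)
    # m1 has only male-specific conditions: absent; m2 carries a
    # female-specific condition (twice, counted once): flagged
    assert flagged == {"m2": {1}}


@pytest.mark.parametrize("seed", [0, 1])
def test_flagging_matches_brute_force(seed):
    ds = generate_cohort(oracle_config(seed=seed))
    cohort = cis_cohort(ds)
    flagged = flag_incongruent_persons(ds, cohort, ORACLE_CONDITIONS)
    assert flagged == brute_flag(ds, cohort, ORACLE_CONDITIONS)
    # flagged persons reconcile exactly with the combined OIR numerator:
    # a person is incongruent only toward the opposite-sex subset, so the
    # subset-sum convention never double-counts them
    combined = compute_oir(ds, cohort, ORACLE_CONDITIONS, "combined")
    assert len(flagged) == combined.n_incongruent


def test_concordance_empty_flagged():
    ds = build_dataset([P("a", "female", "woman")], [], genomic_sex=[G("a", "female")])
    result = genomic_concordance(ds, {})
    assert result.n_flagged == 0
    assert result.match_fraction is None


def test_concordance_requires_genomic_table(small_dataset):
    small_dataset.genomic_sex = None
    with pytest.raises(MissingTableError):
        genomic_concordance(small_dataset, {"p": {1}})


def test_concordance_unknown_calls_not_retrieved():
    ds = build_dataset(
        [P("a", "female", "woman"), P("b", "male", "man"), P("c", "male", "man")],
        [],
        genomic_sex=[G("a", "female"), G("b", "unknown")],
    )
    result = genomic_concordance(ds, {"a": {1}, "b": {1}, "c": {1}})
    assert (result.n_flagged, result.n_retrieved, result.n_matched) == (3, 1, 1)
    assert result.match_fraction == 1.0


def test_concurrence_definition():
    # flagged male carrying both prostate and pregnancy conditions counts
    # toward the male concurrence numerator; a purely incongruent male
    # only toward the denominator
    ds = build_dataset(
        [P("m1", "male", "man"), P("m2", "male", "man"), P("f1", "female", "woman")],
        [O("m1", 1), O("m1", 2), O("m2", 1), O("f1", 1)],
    )
    rates = concurrence_rates(ds, {"m1", "m2", "f1"}, PAIR)
    assert (rates["male"].n_numerator, rates["male"].n_denominator) == (1, 2)
    assert rates["male"].proportion == 0.5
    assert rates["female"].n_denominator == 0
    assert rates["female"].proportion is None


def test_multiplicity_distinctness():
    ds = build_dataset(
        [P("m1", "male", "man"), P("m2", "male", "man")],
        # m1: two distinct incongruent concepts; m2: two records of one
        [O("m1", 1), O("m1", 3), O("m2", 1), O("m2", 1)],
    )
    conds = PAIR + [SexSpecificCondition(3, "Ovarian finding", "female")]
    mult = multiplicity_rates(ds, {"m1", "m2"}, conds)
    assert (mult["incongruent"]["male"].n_numerator,
            mult["incongruent"]["male"].n_denominator) == (1, 2)


def test_multiplicity_all_single_carriers_zero(small_dataset):
    ds = build_dataset(
        [P("f1", "female", "woman"), P("m1", "male", "man")],
        [O("f1", 1), O("m1", 2)],
    )
    mult = multiplicity_rates(ds, {"f1", "m1"}, PAIR)
    for by_sex in mult.values():
        for sp in by_sex.values():
            assert sp.n_numerator == 0


@pytest.mark.parametrize("seed", [3, 4])
def test_concurrence_and_multiplicity_match_brute_force(seed):
    ds = generate_cohort(oracle_config(seed=seed))
    cohort = cis_cohort(ds)
    rates = concurrence_rates(ds, cohort, ORACLE_CONDITIONS)
    expected = brute_concurrence(ds, cohort, ORACLE_CONDITIONS)
    for sex in ("female", "male"):
        assert (rates[sex].n_numerator, rates[sex].n_denominator) == expected[sex]
    mult = multiplicity_rates(ds, cohort, ORACLE_CONDITIONS)
    brute = brute_multiplicity(ds, cohort, ORACLE_CONDITIONS)
    for klass in ("incongruent", "congruent"):
        for sex in ("female", "male"):
            sp = mult[klass][sex]
            assert (sp.n_numerator, sp.n_denominator) == brute[klass][sex]


def test_geography_single_zip3():
    ds = build_dataset(
        [P("a", "female", "woman"), P("b", "male", "man")],
        [O("a", 1), O("b", 1)],
        zip3=[Z("a", "750"), Z("b", "750")],
    )
    rows, summary = geographic_profile(ds, {"a", "b"}, {"b": {1}})
    assert len(rows) == 1
    assert rows.iloc[0]["population_fraction"] == 1.0
    assert rows.iloc[0]["incongruent_fraction"] == 1.0
    assert summary["pearson_r"] is None


def test_geography_fractions_sum_to_one_and_match_brute(small_dataset, small_cohort):
    flagged = flag_incongruent_persons(small_dataset, small_cohort, ORACLE_CONDITIONS)
    rows, summary = geographic_profile(small_dataset, small_cohort, flagged)
    assert rows["population_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
    assert rows["incongruent_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
    brute = brute_geography(small_dataset, small_cohort, flagged)
    assert {
        r.zip3: (r.n_persons, r.n_incongruent) for r in rows.itertuples(index=False)
    } == brute
    assert summary["n_zip3_with_flagged"] == sum(1 for _, i in brute.values() if i)


def test_geography_zero_flagged_zip_removal_invariant(small_dataset, small_cohort):
    """Dropping a zip3 with no flagged persons leaves every other zip3's
    incongruent share unchanged."""
    flagged = flag_incongruent_persons(small_dataset, small_cohort, ORACLE_CONDITIONS)
    rows, _ = geographic_profile(small_dataset, small_cohort, flagged)
    empty = rows[rows["n_incongruent"] == 0]
    if empty.empty:
        pytest.skip("fixture produced flagged persons in every zip3")
    drop_zip = empty.iloc[0]["zip3"]
    keep = {
        p for p in small_cohort
        if not ((small_dataset.zip3["person_id"] == p)
                & (small_dataset.zip3["zip3"] == drop_zip)).any()
    }
    rows2, _ = geographic_profile(small_dataset, keep, flagged)
    merged = rows.merge(rows2, on="zip3", suffixes=("_a", "_b"))
    assert (merged["incongruent_fraction_a"] == merged["incongruent_fraction_b"]).all()


def test_geography_tracks_population_under_uniform_misassignment():
    """When errors land uniformly, zip3 incongruent shares track
    population shares and their correlation is high."""
    ds = generate_cohort(oracle_config(seed=8, n_persons=30_000, error_rate=0.05))
    cohort = cis_cohort(ds)
    flagged = flag_incongruent_persons(ds, cohort, ORACLE_CONDITIONS)
    rows, summary = geographic_profile(ds, cohort, flagged)
    assert summary["pearson_r"] > 0.8


def test_temporal_profile_empty_conditions(small_dataset, small_cohort):
    assert temporal_profile(small_dataset, small_cohort, []).empty


def test_temporal_profile_single_year():
    ds = build_dataset(
        [P("f1", "female", "woman"), P("m1", "male", "man")],
        [O("f1", 1, "2019-03-01"), O("f1", 1, "2019-11-11"), O("m1", 1, "2019-06-30")],
    )
    profile = temporal_profile(ds, {"f1", "m1"}, [FEMALE_COND])
    assert set(profile["year"]) == {2019}
    by_class = profile.set_index("congruence_class")["n_records"]
    assert by_class["congruent"] == 2   # f1's records
    assert by_class["incongruent"] == 1  # m1 is flagged


def test_temporal_profile_uniform_years():
    """Uniform generator start dates yield per-class year histograms
    compatible with a uniform multinomial."""
    ds = generate_cohort(oracle_config(seed=5, n_persons=5000,
                                       year_range=(2010, 2019)))
    cohort = cis_cohort(ds)
    profile = temporal_profile(ds, cohort, ORACLE_CONDITIONS)
    sub = profile[(profile["sex_specificity"] == "female_specific")
                  & (profile["congruence_class"] == "congruent")]
    observed = sub.set_index("year")["n_records"].reindex(range(2010, 2020), fill_value=0)
    assert stats.chisquare(observed).pvalue > 1e-3


def test_sensitivity_identical_for_all_cisgender_cohort():
    ds = generate_cohort(oracle_config(
        seed=6,
        gender_identity_distribution={"female": {"woman": 1.0}, "male": {"man": 1.0}},
    ))
    cohort = cis_cohort(ds)
    primary = compute_oir(ds, cohort, ORACLE_CONDITIONS, "combined")
    sens, composition = sensitivity_noncisgender(ds, ORACLE_CONDITIONS)
    assert (sens.n_incongruent, sens.n_congruent) == (
        primary.n_incongruent, primary.n_congruent
    )
    assert composition["fraction_all"].sum() == pytest.approx(1.0)
    assert composition["fraction_flagged"].sum() == pytest.approx(1.0)


def test_sensitivity_inflates_with_noncisgender_cross_sex_conditions():
    """Non-cisgender participants carrying opposite-sex conditions (e.g.
    post gender-affirming care) inflate the inclusive OIR."""
    persons = [P(f"f{i}", "female", "woman") for i in range(60)]
    occurrences = [O(f"f{i}", 1) for i in range(60)]
    persons += [P("m0", "male", "man")]
    occurrences += [O("m0", 1)]  # one cisgender incongruent record
    # transgender participants (sex male, gender woman) with the
    # female-specific condition as a true diagnosis
    persons += [P(f"t{i}", "male", "woman") for i in range(5)]
    occurrences += [O(f"t{i}", 1) for i in range(5)]
    persons += [P("mm", "male", "man")]
    occurrences += [O("mm", 2)]  # keeps the male-specific subset nonempty
    ds = build_dataset(persons, occurrences)
    cohort = cis_cohort(ds)
    primary = compute_oir(ds, cohort, PAIR, "combined")
    sens, composition = sensitivity_noncisgender(ds, PAIR)
    assert sens.rate > primary.rate
    woman_row = composition.set_index("gender_identity")["fraction_flagged"]
    assert woman_row["woman"] > 0  # trans women appear among flagged persons
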