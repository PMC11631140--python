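"""Condition screening: sex counts, thresholds, and their boundaries."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import O, P, build_dataset, cis_cohort, oracle_config
from oracles import brute_count_by_sex
from sexcheck import Dataset, ScreenConfig, count_by_sex, generate_cohort, screen_conditions
from sexcheck.screen import COUNT_COLUMNS


def counts_row(concept_id, n_female, n_male, name=""):
    n_total = n_female + n_male
    if n_female > n_male:
        majority, frac = "female", n_female / n_total
    elif n_male > n_female:
        majority, frac = "male", n_male / n_total
    else:
        majority, frac = "none", (n_female / n_total if n_total else float("nan"))
    return dict(concept_id=concept_id, concept_name=name, n_female=n_female,
                n_male=n_male, n_total=n_total, majority_sex=majority,
                majority_fraction=frac)


def counts_table(*rows) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=COUNT_COLUMNS)


def test_count_by_sex_counts_persons_not_records():
    ds = build_dataset(
        [P("f1", "female", "woman")],
        [O("f1", 111) for _ in range(5)],
    )
    counts = count_by_sex(ds, {"f1"})
    row = counts.iloc[0]
    assert (row["n_female"], row["n_male"], row["n_total"]) == (1, 0, 1)


def test_count_by_sex_majority_fraction_pregnancy_scale():
    """A condition carried by 22625 females and 209 males has majority
    fraction 22625/22834 ≈ 0.9908 — biased but short of perfect."""
    n_f, n_m = 22625, 209
    persons = pd.DataFrame({
        "person_id": [f"p{i}" for i in range(n_f + n_m)],
        "sex_at_birth": ["female"] * n_f + ["male"] * n_m,
        "gender_identity": ["woman"] * n_f + ["man"] * n_m,
    })
    occurrences = pd.DataFrame({
        "person_id": persons["person_id"],
        "concept_id": 777,
        "start_date": "2020-01-01",
    })
    ds = Dataset.from_records(persons, occurrences)
    counts = count_by_sex(ds, set(persons["person_id"]))
    row = counts.iloc[0]
    assert (row["n_female"], row["n_male"]) == (n_f, n_m)
    assert row["majority_sex"] == "female"
    assert row["majority_fraction"] == pytest.approx(22625 / 22834)
    assert round(row["majority_fraction"], 4) == 0.9908


def test_count_by_sex_matches_brute_force():
    ds = generate_cohort(oracle_config(seed=13, n_persons=500))
    cohort = cis_cohort(ds)
    counts = count_by_sex(ds, cohort)
    expected = brute_count_by_sex(ds, cohort)
    assert set(counts["concept_id"]) == set(expected)
    for row in counts.itertuples(index=False):
        assert (row.n_female, row.n_male) == expected[int(row.concept_id)]


@pytest.mark.parametrize(
    "n_female,n_male,name,selected",
    [
        (19, 0, "x", False),    # below the 20-participant floor
        (950, 50, "x", False),  # 0.95 is not > 0.95 (strict)
        (999, 1, "Ovarian cyst", True),
        (1000, 0, "x", True),   # exactly 1000 participants kept
        (999, 0, "x", False),   # below the 1000-participant prevalence cut
        (5000, 5000, "x", False),  # tie: no majority sex
        (2000, 1, "Benign breast lump", False),  # name exclusion
        (2000, 1, "MAMMARY abnormality", False),  # case-insensitive
    ],
)
def test_screen_boundaries(n_female, n_male, name, selected):
    counts = counts_table(counts_row(1, n_female, n_male, name))
    result = screen_conditions(counts, None, ScreenConfig())
    assert (len(result.selected) == 1) is selected
    if selected:
        assert result.selected.iloc[0]["specific_sex"] == "female"


def test_exactly_twenty_survives_participant_floor():
    counts = counts_table(counts_row(1, 20, 0, "x"))
    result = screen_conditions(
        counts, None, ScreenConfig(min_prevalent_participants=1)
    )
    assert len(result.selected) == 1


def test_manual_exclusion_list():
    counts = counts_table(counts_row(1, 2000, 1, "a"), counts_row(2, 2000, 1, "b"))
    cfg = ScreenConfig(manual_exclusion_concept_ids=[2])
    result = screen_conditions(counts, None, cfg)
    assert list(result.selected["concept_id"]) == [1]


def test_stage_log_records_every_filter():
    counts = counts_table(
        counts_row(1, 5, 0, "tiny"),
        counts_row(2, 900, 100, "balanced-ish"),
        counts_row(3, 2000, 10, "kept"),
        counts_row(4, 3000, 20, "breast finding"),
        counts_row(5, 400, 2, "prevalent enough? no"),
    )
    result = screen_conditions(counts, None, ScreenConfig())
    stages = dict(result.stages)
    assert stages["candidate_conditions"] == 5
    assert stages["min_participant_filter"] == 4
    assert stages["sex_bias_filter"] == 3
    assert stages["name_exclusion"] == 2
    assert stages["prevalence_filter"] == 1
    assert stages["manual_exclusion"] == 1
    assert list(result.selected["concept_id"]) == [3]


def test_selected_satisfy_thresholds_post_hoc(small_dataset, small_cohort):
    cfg = ScreenConfig(min_condition_participants=5, min_prevalent_participants=10)
    counts = count_by_sex(small_dataset, small_cohort)
    result = screen_conditions(counts, small_dataset.concepts, cfg)
    sel = result.selected
    assert (sel["majority_fraction"] > cfg.bias_threshold).all()
    assert (sel["n_total"] >= cfg.min_prevalent_participants).all()


def test_catalogue_recovery_on_synthetic_cohort():
    """With small ε and large prevalence·n, screening recovers every
    prevalent sex-specific catalogue condition with the correct sex."""
    ds = generate_cohort(oracle_config(seed=2, n_persons=2000, error_rate=0.01))
    cohort = cis_cohort(ds)
    counts = count_by_sex(ds, cohort)
    cfg = ScreenConfig(min_prevalent_participants=50)
    selected = screen_conditions(counts, ds.concepts, cfg).selected
    by_id = selected.set_index("concept_id")["specific_sex"]
    assert by_id.to_dict() == {11: "female", 12: "female", 21: "male", 22: "male"}


_fixture_counts = counts_table(
    counts_row(1, 25, 0, "a"),
    counts_row(2, 1500, 60, "b"),
    counts_row(3, 1200, 20, "c"),
    counts_row(4, 30, 1300, "d"),
    counts_row(5, 980, 15, "e"),
    counts_row(6, 4000, 150, "f"),
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    min_participants=st.integers(1, 50),
    bias=st.floats(0.51, 0.99),
    min_prevalent=st.integers(1, 2000),
    stricter=st.tuples(st.integers(0, 30), st.floats(0, 0.009), st.integers(0, 500)),
)
def test_threshold_monotonicity(min_participants, bias, min_prevalent, stricter):
    """Raising any threshold never enlarges the selected set."""
    loose = ScreenConfig(
        min_condition_participants=min_participants,
        bias_threshold=bias,
        min_prevalent_participants=min_prevalent,
    )
    tight = ScreenConfig(
        min_condition_participants=min_participants + stricter[0],
        bias_threshold=min(bias + stricter[1], 0.999),
        min_prevalent_participants=min_prevalent + stricter[2],
    )
    selected_loose = set(screen_conditions(_fixture_counts, None, loose).selected["concept_id"])
    selected_tight = set(screen_conditions(_fixture_counts, None, tight).selected["concept_id"])
    assert selected_tight <= selected_loose
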