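# Methods

## Setting and assumptions

The package assesses plausibility/concordance of EHR condition data by
exploiting conditions that are biologically exclusive to one sex. The
approach assumes:

* an adult cohort — developmental sex characteristics in pediatric
  populations would need a different framework;
* survey sex at birth is reliable, which is checked (not assumed) via the
  genomic concordance operation: in the reference study the genomic-inferred
  sex of flagged participants matched the survey perfectly, placing the
  blame on EHR logging/extraction rather than self-report;
* gender-diverse participants may carry cross-sex conditions as true
  diagnoses (e.g. after gender-affirming care), so the primary analysis is
  restricted to cisgender-conforming participants and the inclusive cohort
  is a separate sensitivity analysis, not an error measurement.

## The incongruence rate

For one screened condition, `CIR = N_incongruent / N_total` over distinct
participants carrying the condition. The overall rate pools a condition
set: per specificity subset, `N_total` is the number of distinct persons
carrying ≥1 listed condition of that specificity and `N_incongruent` the
subset of the non-matching sex. The combined OIR **sums** the
female-specific and male-specific subset counts — a person carrying both a
female- and a male-specific condition contributes to both subsets. This
summation convention is used because it is the arithmetic that the
reference study's published counts satisfy exactly (849+285 = 1134
incongruent; 95 015+35 875 = 130 890 congruent).

Intervals are Wald: `p ± z·√(p(1−p)/n)`, z = 1.96 by default, never
clamped to [0, 1] (published per-condition intervals have negative lower
bounds; a `clamp` flag exists, default off). Two `n` conventions are
implemented because the reference tables are internally inconsistent:

* `total` (default): `n = N_total`, the formula's natural sample size;
  reproduces the published *overall* intervals.
* `incongruent`: `n = N_incongruent`; mathematically unconventional, but it
  is the only convention that reproduces the published *per-condition*
  intervals (verified for every non-erratum row bundled in
  `sexcheck.published`). Reports record which convention produced each CI.

A second inconsistency is handled the same way: the "Drug dependence in
mother…" reference row prints a rate equal to incongruent/congruent rather
than incongruent/total. The package implements the formula, stores the row
with a `rate_erratum` flag, and excludes it from reproduction checks.

## Condition screening

Counts are always *distinct participants*; record multiplicity is
deduplicated at counting time, because the screening thresholds and the
published counts are participant-based. Stages, in order:

1. **Participant floor** — drop conditions occurring in fewer than 20
   participants (exactly 20 is kept).
2. **Sex-bias rule** — keep conditions whose majority-sex fraction is
   strictly greater than 0.95 (an analogue of the 5% significance
   convention). Exactly 95.0% fails; a tie has no majority sex and can
   never pass.
3. **Name exclusions** — case-insensitive substring filters, default
   `breast`, `mammary`: breast findings are female-biased but occur in
   males, so they are not sex-exclusive.
4. **Prevalence cut** — keep conditions with ≥1000 participants; rarer
   conditions make single errors look like large rates.
5. **Manual exclusion list** — explicit concept ids standing in for
   clinical review of sex-biased-but-not-exclusive conditions (e.g.
   hirsutism); empty by default.

The bias rule is applied before the name exclusion (the order the screening
procedure is usually described in); both stage counts are logged so either
ordering is auditable. Raising any threshold can only shrink the selection
(a tested invariant).

## Synthetic cohorts and the error model

The generator emulates the structure the analysis needs, not clinical
realism:

* sexes drawn i.i.d. with `female_fraction` (default 0.62, matching the
  roughly 3:2 female:male composition of large US volunteer cohorts);
* gender identity drawn per sex; the default puts ~96% at the
  sex-conforming category with small transgender/nonbinary/other/skip
  fractions, of the order reported for *All of Us* (≈1% with gender
  differing from sex at birth, a few percent non-answers);
* each condition in the catalogue is carried by members of its target pool
  independently with its prevalence; a carrier generates
  `K = 1 + Poisson(records_per_carrier − 1)` records (default mean 3),
  reflecting that EHR conditions recur across visits;
* condition start dates are uniform over `year_range` (default 2000–2022);
* zip3 areas are assigned to every person with a condition record,
  proportional to configurable weights (default: 20 heterogeneous
  metro-like weights);
* genomic-inferred sex equals sex at birth except with
  `genomic_mismatch_rate` (default 0) for a `genomic_coverage` fraction of
  persons (default 1).

**Error injection.** The default mechanism is *record-level
mis-assignment*: each record of a sex-specific condition is, independently
with probability ε (`error_rate`, default 0.01), attached to a uniformly
chosen person of the opposite sex instead of its carrier. This mechanism
was chosen because it reproduces two signatures of real incongruent
participants: they retain congruent conditions too (a mix of accurate and
erroneous records), and their geographic spread tracks population size. A
`person_swap` mode (a carrier's entire record set for one condition moves
to one opposite-sex person) is provided for contrast; no claim is made
about which mechanism operates in real data. If no opposite-sex person
exists, records stay with their carrier (ε effectively 0).

What the generator does **not** emulate: disease co-occurrence structure,
age, visit-level longitudinal structure, provider/site clustering of
errors, and any correlation between gender identity and condition risk.
Passing parameter-recovery tests therefore demonstrates internal
consistency of the estimator under the stated error model, not performance
on real EHR data.

## Analytic expected OIR

`expected_oir` returns the ratio of expected incongruent to expected total
distinct-person counts implied by a configuration. With pgf
`g(t) = t·exp((r−1)(t−1))` for the per-carrier record count (mean r), the
record-mis-assignment model gives, for a subset of conditions with source
pool size `n_src`, target pool `n_tgt` and cisgender retention fractions
`c_src`, `c_tgt`:

* P(opposite-sex person receives no record of condition c) =
  `(1 − q·(1 − g(1 − ε/n_tgt)))^n_src`,
* P(a carrier retains ≥1 own record) = `1 − g(ε)`,

multiplied over conditions and combined as
`E[inc] = c_tgt·n_tgt·(1 − Π no-hit)`,
`E[cong] = c_src·n_src·(1 − Π(1 − q·retain))`. The `person_swap` mode
replaces the per-condition terms with `q·ε/n_tgt` and `1 − ε`. Pool sizes
use expectations (`n·f`, `n·(1−f)`), so this is a ratio of expectations —
the O(1/n) difference from the expectation of the ratio is negligible at
the cohort sizes used, and agreement with brute-force simulation within
Monte-Carlo error is part of the test suite for both modes. The value
assumes every sex-specific catalogue condition enters the rate (true
whenever prevalence·n comfortably clears the screening cuts).

## Profiling definitions

* **Flagging**: a person is incongruent if they carry ≥1 screened condition
  whose specific sex differs from their sex at birth.
* **Concurrence / multiplicity**: "congruent condition" means membership in
  the screened list only, not any EHR condition, so the two classes are
  defined on the same footing. Multiplicity requires distinct concepts;
  repeated records of one concept never count.
* **Genomic concordance**: retrieval requires a determinate female/male
  call; `unknown` calls count as not retrieved.
* **Geography**: shares (not counts) per zip3 — the zip3's fraction of the
  profiled population against its fraction of flagged persons; the summary
  Pearson correlation is computed on these fractions over zip3s containing
  flagged persons, matching how the relationship is usually plotted.
  Pearson was chosen because the expected relationship under uniform
  mis-assignment is linear through the origin.
* **Temporal**: record counts per calendar start year, split by condition
  specificity and by the person's congruence class.
* **Sensitivity**: the combined OIR recomputed on all binary-sex persons;
  the gender-composition table removes skip/prefer-not-to-answer before
  taking fractions, since non-answers say nothing about gender diversity.

## Numerical and degenerate-input choices

* Empty denominators raise `UndefinedRateError` — a rate is never silently
  reported as 0 when no one carries the conditions.
* `p = 0` gives a zero-width Wald interval; in the `incongruent`-n
  convention with zero incongruent persons the interval degenerates to the
  point rate.
* Small-cell masking replaces counts strictly below the threshold
  (default 20) with `"<20"` and masks derived rates on those rows; exact
  tables are kept internally, masked variants carry the `_public` suffix.
* Duplicate `person_id` rows are a fatal load error (no resolution rule is
  defensible without provenance); occurrences referencing unknown persons
  are fatal under strict loading and logged-and-dropped otherwise.
* Determinism: one `numpy` Generator seeded from the config; categorical
  draws iterate sorted category keys so dict insertion order is irrelevant.
  Identical configs produce bit-identical datasets and, through the
  pipeline, byte-identical outputs (manifest timestamp aside).

## Problem sizes used in validation

Oracle-equivalence checks run 20 fixtures of 600 persons with ε = 0.10
(high enough that every statistic has nonzero cells). Parameter recovery
runs 100 cohorts of 50 000 persons with one female- and one male-specific
condition at prevalence 0.2 and ε = 0.01; the combined-OIR Wald interval
covers the analytic expectation in ≥93 of 100 runs and the mean estimate
sits within a few percent of it. Wald coverage itself is checked against
its exact value (94.6% at p = 0.01, n = 10 000) by simulation.

## Known limitations

* The screening cannot distinguish sex-exclusive from strongly sex-biased
  conditions without the manual exclusion list; the default name filters
  cover only breast/mammary findings.
* The published 167-condition reference list is not bundled (it derives
  from access-restricted data); users with access can supply it as an
  allow-list via the screening configuration.
* The incongruence rate measures *detectable* error only: errors between
  same-sex persons, or in sex-neutral conditions, are invisible to it, so
  the true record-error rate is strictly higher than any IR.
* Geography and time profiles describe spread; no formal spatial or
  temporal test is implemented.
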