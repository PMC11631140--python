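# sexcheck

**Sex-incongruence data-quality assessment for OMOP-style EHR condition data.**

Electronic health records accumulate logging and extraction errors, and most
are invisible: a mis-attached diagnosis usually looks plausible. Conditions
that are biologically exclusive to one sex are the exception — a prostate
neoplasm recorded for a biological female, or a pregnancy finding for a
biological male, is almost certainly a data error once gender-diverse
participants are handled separately. `sexcheck` turns this observation into a
quantitative plausibility/concordance check for research cohorts stored in
(a reduced form of) the OMOP common data model, such as the *All of Us*
Research Program EHR tables. It is aimed at data-quality engineers and
epidemiologists who need a scalar, comparable measure of record integrity.

## The statistic

For a screened sex-specific condition *cs*, the **condition-specific
incongruence rate** is

```
CIR = N_incongruent,cs / N_total,cs
```

where counts are *distinct participants* (never records), and a participant
is incongruent when their survey sex at birth conflicts with the condition's
specific sex. Because per-condition rates are noisy, conditions are pooled
into an **overall incongruence rate**

```
OIR = N_incongruent,overall / N_total,overall
```

computed person-level per specificity subset (female-specific,
male-specific); the combined OIR sums the two subsets' counts. Uncertainty
is a Wald interval `p ± z·√(p(1−p)/n)` (z = 1.96), deliberately unclamped.

The pipeline around the statistic:

1. **Cohort selection** — binary sex at birth, optionally cisgender-conforming
   gender identity only, at least one EHR condition record.
2. **Condition screening** — per-condition distinct-participant counts by
   sex; keep conditions with ≥20 participants, >95% of participants in a
   single sex (strict), no breast/mammary findings, ≥1000 participants, and
   not on a manual exclusion list.
3. **Rates** — CIR per condition, OIR per subset, Wald intervals, small-cell
   masking (counts <20) for public tables.
4. **Profiling** — genomic-sex concordance of flagged participants,
   concurrent congruent conditions, incongruence multiplicity, zip3
   geography, condition-start-year histograms, and a sensitivity analysis
   including non-cisgender participants.
5. **Synthetic cohorts** — a generator that injects a configurable
   record-mis-assignment error rate ε, with a closed-form expected OIR for
   parameter-recovery validation.

## Worked example

```python
import sexcheck as sc

cfg = sc.SyntheticConfig(n_persons=20_000, error_rate=0.01, seed=11)
ds = sc.generate_cohort(cfg)                       # OMOP-lite Dataset
cohort = sc.restrict_to_ehr(ds, sc.select_cohort(ds))
counts = sc.count_by_sex(ds, cohort)
result = sc.screen_conditions(counts, ds.concepts,
                              sc.ScreenConfig(min_prevalent_participants=300))
print(result.stages)
est = sc.compute_oir(ds, cohort, result.selected, "combined")
print(f"combined OIR = {est.rate:.4%}  [{est.ci_low:.4%}, {est.ci_high:.4%}]  "
      f"({est.n_incongruent}/{est.n_total})")
```

prints

```
[('candidate_conditions', 13), ('min_participant_filter', 12),
 ('sex_bias_filter', 9), ('name_exclusion', 8), ('prevalence_filter', 5),
 ('manual_exclusion', 5)]
combined OIR = 3.0339%  [2.4541%, 3.6137%]  (102/3362)
```

Reading: of the 13 catalogue conditions recorded in this cohort, 5 survive
screening (the prevalence cut was lowered to 300 for this small cohort); of
the 3362 distinct participants carrying a screened sex-specific condition,
102 carry one incongruent with their sex at birth. The 3% rate is higher
than the injected ε = 1% because each mis-assigned record can flag a
participant who carries only that single record, while congruent carriers
are counted once however many conditions they have.

The generator's analytic expectation closes the loop. With a catalogue of
one female-specific and one male-specific condition (prevalence 0.2,
ε = 0.01, 50 000 persons, seed 11) the full screen-then-rate pipeline gives

```
observed OIR = 0.02812  CI [0.02484, 0.03139]
expected OIR = 0.02906
```

i.e. the interval covers `sc.expected_oir(cfg)`.

The same pipeline runs from a shell:

```bash
sexcheck simulate --config sim.yaml --out data/
sexcheck run --config run.yaml --in data/ --out results/
sexcheck report --in results/ --public     # applies <20 masking
```

## Layout

```
src/sexcheck/
  types.py      OMOP-lite domain types and the Dataset container
  io.py         CSV dialect readers/writers
  synthetic.py  cohort generator + analytic expected OIR
  cohort.py     participant filters
  screen.py     sex-specific condition screening
  metrics.py    CIR/OIR, Wald intervals, small-cell masking
  profile.py    flagged-participant characterization
  published.py  published reference counts used as arithmetic inputs
  config.py, pipeline.py, cli.py   config-driven orchestration + CLI
```

See `docs/methods.md` for the statistical model, the error-injection
mechanisms, and the design decisions behind the screening rules.
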