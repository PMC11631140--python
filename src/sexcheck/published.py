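"""Published reference counts from the All of Us v7 sex-incongruence audit.

These are the reported incongruent/congruent distinct-participant
counts for the six sex-specific conditions with the highest
incongruence and for the three collective condition sets, together
with the rates and Wald intervals as printed.  They serve as arithmetic
inputs for cross-checking :mod:`sexcheck.metrics`: recomputing the rate
and interval from the counts must reproduce the printed values.

One caveat is recorded explicitly: the "Drug dependence in mother…"
row's printed rate equals incongruent/congruent instead of
incongruent/total (an apparent erratum), so it is flagged with
``rate_erratum`` and excluded from rate-reproduction checks.  The
printed per-condition intervals follow an ``n = N_incongruent``
convention rather than the rate formula's ``n = N_total``; the overall
rows use ``n = N_total``.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PublishedRow:
    label: str
    n_incongruent: int
    n_congruent: int
    printed_rate: float
    printed_ci: tuple[float, float]
    ci_n_mode: str  # "total" or "incongruent" — which n reproduces the printed CI
    concept_id: int | None = None
    specific_sex: str | None = None
    rate_erratum: bool = False


TOP_CONDITIONS: tuple[PublishedRow, ...] = (
    PublishedRow(
        label="Drug dependence in mother complicating pregnancy, childbirth, AND/OR puerperium",
        concept_id=440787, specific_sex="female",
        n_incongruent=27, n_congruent=1005,
        printed_rate=0.0269, printed_ci=(-0.034, 0.088),
        ci_n_mode="incongruent", rate_erratum=True,
    ),
    PublishedRow(
        label="Female infertility", concept_id=201909, specific_sex="female",
        n_incongruent=102, n_congruent=3715,
        printed_rate=0.0267, printed_ci=(-0.0046, 0.058),
        ci_n_mode="incongruent",
    ),
    PublishedRow(
        label="Primary ovarian failure", concept_id=4279913, specific_sex="female",
        n_incongruent=62, n_congruent=3591,
        printed_rate=0.0170, printed_ci=(-0.015, 0.049),
        ci_n_mode="incongruent",
    ),
    PublishedRow(
        label="Inflammatory disorder of male genital organ",
        concept_id=197605, specific_sex="male",
        n_incongruent=42, n_congruent=1361,
        printed_rate=0.0299, printed_ci=(-0.022, 0.081),
        ci_n_mode="incongruent",
    ),
    PublishedRow(
        label="Testicular hypofunction", concept_id=26662, specific_sex="male",
        n_incongruent=44, n_congruent=4157,
        printed_rate=0.0105, printed_ci=(-0.02, 0.041),
        ci_n_mode="incongruent",
    ),
    PublishedRow(
        label="Primary malignant neoplasm of prostate",
        concept_id=200962, specific_sex="male",
        n_incongruent=55, n_congruent=5770,
        printed_rate=0.00944, printed_ci=(-0.016, 0.035),
        ci_n_mode="incongruent",
    ),
)

OVERALL: dict[str, PublishedRow] = {
    "female_specific": PublishedRow(
        label="151 female-specific conditions",
        n_incongruent=849, n_congruent=95015,
        printed_rate=0.00886, printed_ci=(0.0083, 0.0094),
        ci_n_mode="total",
    ),
    "male_specific": PublishedRow(
        label="16 male-specific conditions",
        n_incongruent=285, n_congruent=35875,
        printed_rate=0.00788, printed_ci=(0.007, 0.0088),
        ci_n_mode="total",
    ),
    "combined": PublishedRow(
        label="167 female or male-specific conditions",
        n_incongruent=1134, n_congruent=130890,
        printed_rate=0.00859, printed_ci=(0.0081, 0.0091),
        ci_n_mode="total",
    ),
}

#: combined OIR as printed in the study's headline, percent to 2 decimals
HEADLINE_OIR_PERCENT = 0.86
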