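"""End-to-end orchestration: cohort → screen → metrics → profile.

``run_pipeline`` executes the requested stages in dependency order on
either a loaded OMOP-lite directory or a generated synthetic cohort,
writes every stage's tables (exact and small-cell-masked public
variants) under the output directory, and finishes with a manifest of
content hashes so reruns can be verified byte-for-byte (the manifest's
timestamp is the only non-deterministic field).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .cohort import restrict_to_ehr, selection_flow
from .config import RunConfig
from .io import load_dataset
from .metrics import compute_cir, compute_oir, mask_small_counts, UndefinedRateError
from .profile import (
    flag_incongruent_persons,
    genomic_concordance,
    geographic_profile,
    multiplicity_rates,
    concurrence_rates,
    sensitivity_noncisgender,
    temporal_profile,
)
from .screen import ScreenResult, count_by_sex, screen_conditions
from .synthetic import generate_cohort
from .types import Dataset, MissingTableError

log = logging.getLogger(__name__)

CONDITIONS_FILE = "sex_specific_conditions.csv"

RATE_COUNT_COLS = ["n_incongruent", "n_congruent"]
RATE_FLOAT_COLS = ["rate", "ci_low", "ci_high"]


class PipelineDependencyError(RuntimeError):
    """A requested stage is missing a prerequisite stage's output."""


@dataclass
class ReportBundle:
    output_dir: Path
    manifest: dict
    files: dict[str, Path]

    @property
    def status(self) -> str:
        return self.manifest["status"]


def _estimate_row(est) -> dict:
    return {
        "label": est.label,
        "n_incongruent": est.n_incongruent,
        "n_congruent": est.n_congruent,
        "n_total": est.n_total,
        "rate": est.rate,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "z": est.z,
        "ci_n_mode": est.ci_n_mode,
    }


def _write_csv(df: pd.DataFrame, path: Path, files: dict[str, Path]) -> None:
    df.to_csv(path, index=False)
    files[path.name] = path


def _public_variant(df: pd.DataFrame, path: Path, threshold: int,
                    files: dict[str, Path],
                    count_columns=None, rate_columns=None) -> None:
    public = mask_small_counts(df, threshold, count_columns, rate_columns)
    out = path.with_name(path.stem + "_public.csv")
    public.to_csv(out, index=False)
    files[out.name] = out


def _load_conditions(out: Path) -> pd.DataFrame:
    path = out / CONDITIONS_FILE
    if not path.is_file():
        raise PipelineDependencyError(
            f"stage requires the screen stage output ({CONDITIONS_FILE}); "
            "include 'screen' in stages or point output_dir at a prior run"
        )
    return pd.read_csv(path)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the configured stages and write a report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    notes: list[str] = []

    if config.synthetic is not None:
        dataset = generate_cohort(config.synthetic)
    else:
        dataset = load_dataset(config.input_dir, strict=config.strict_load)

    # participant funnel (always computed; cheap and every stage needs it)
    policy = config.cohort.to_policy()
    cohort, steps = selection_flow(dataset, policy)
    cohort = restrict_to_ehr(dataset, cohort)
    steps.append(("with_ehr_conditions", len(cohort)))
    _write_csv(pd.DataFrame(steps, columns=["step", "n_remaining"]),
               out / "flowchart_counts.csv", files)

    stages = list(config.stages)
    conditions: pd.DataFrame | None = None
    screen_result: ScreenResult | None = None

    if "screen" in stages:
        counts = count_by_sex(dataset, cohort)
        screen_result = screen_conditions(counts, dataset.concepts, config.screen)
        conditions = screen_result.selected
        _write_csv(conditions, out / CONDITIONS_FILE, files)
        _write_csv(
            pd.DataFrame(screen_result.stages, columns=["stage", "n_conditions_remaining"]),
            out / "screen_log.csv", files,
        )

    def need_conditions() -> pd.DataFrame:
        nonlocal conditions
        if conditions is None:
            conditions = _load_conditions(out)
        return conditions

    if "metrics" in stages:
        cond = need_conditions()
        cir_rows = []
        for row in cond.itertuples(index=False):
            try:
                est = compute_cir(dataset, cohort, row, config.z, config.ci_n_mode)
            except UndefinedRateError:
                continue
            r = _estimate_row(est)
            r.update(concept_id=int(row.concept_id), specific_sex=row.specific_sex)
            cir_rows.append(r)
        cir = pd.DataFrame(
            cir_rows,
            columns=["concept_id", "label", "specific_sex", *RATE_COUNT_COLS,
                     "n_total", *RATE_FLOAT_COLS, "z", "ci_n_mode"],
        )
        _write_csv(cir, out / "cir_table.csv", files)
        _public_variant(cir, out / "cir_table.csv", config.mask_threshold, files,
                        RATE_COUNT_COLS + ["n_total"], RATE_FLOAT_COLS)

        oir_rows = []
        for subset in ("female_specific", "male_specific", "combined"):
            try:
                est = compute_oir(dataset, cohort, cond, subset, config.z)
            except UndefinedRateError as exc:
                notes.append(f"oir {subset} skipped: {exc}")
                continue
            r = _estimate_row(est)
            r["subset"] = subset
            oir_rows.append(r)
        oir = pd.DataFrame(
            oir_rows,
            columns=["subset", "label", *RATE_COUNT_COLS, "n_total",
                     *RATE_FLOAT_COLS, "z", "ci_n_mode"],
        )
        _write_csv(oir, out / "oir_table.csv", files)
        _public_variant(oir, out / "oir_table.csv", config.mask_threshold, files,
                        RATE_COUNT_COLS + ["n_total"], RATE_FLOAT_COLS)

    if "profile" in stages:
        cond = need_conditions()
        flagged = flag_incongruent_persons(dataset, cohort, cond)

        try:
            conc = genomic_concordance(dataset, flagged)
            (out / "concordance.json").write_text(
                json.dumps(dataclasses.asdict(conc), indent=2) + "\n"
            )
            files["concordance.json"] = out / "concordance.json"
        except MissingTableError as exc:
            notes.append(f"concordance skipped: {exc}")

        try:
            rates = concurrence_rates(dataset, cohort, cond)
            conc_df = pd.DataFrame(
                [{"sex": s, "n_with_congruent": sp.n_numerator,
                  "n_flagged": sp.n_denominator, "proportion": sp.proportion}
                 for s, sp in rates.items()]
            )
            _write_csv(conc_df, out / "concurrence.csv", files)
            _public_variant(conc_df, out / "concurrence.csv", config.mask_threshold,
                            files, ["n_with_congruent", "n_flagged"], ["proportion"])
        except ValueError as exc:
            notes.append(f"concurrence skipped: {exc}")

        mult = multiplicity_rates(dataset, cohort, cond)
        mult_df = pd.DataFrame(
            [{"congruence_class": klass, "sex": s,
              "n_multiple": sp.n_numerator, "n_with_class": sp.n_denominator,
              "proportion": sp.proportion}
             for klass, by_sex in mult.items() for s, sp in by_sex.items()]
        )
        _write_csv(mult_df, out / "multiplicity.csv", files)
        _public_variant(mult_df, out / "multiplicity.csv", config.mask_threshold,
                        files, ["n_multiple", "n_with_class"], ["proportion"])

        try:
            zrows, zsummary = geographic_profile(dataset, cohort, flagged)
            _write_csv(zrows, out / "zip3_profile.csv", files)
            _public_variant(zrows, out / "zip3_profile.csv", config.mask_threshold,
                            files, ["n_persons", "n_incongruent"],
                            ["population_fraction", "incongruent_fraction"])
            (out / "zip3_summary.json").write_text(json.dumps(zsummary, indent=2) + "\n")
            files["zip3_summary.json"] = out / "zip3_summary.json"
        except MissingTableError as exc:
            notes.append(f"geography skipped: {exc}")

        tp = temporal_profile(dataset, cohort, cond)
        _write_csv(tp, out / "temporal_profile.csv", files)
        _public_variant(tp, out / "temporal_profile.csv", config.mask_threshold,
                        files, ["n_records"], [])

    if "sensitivity" in stages:
        cond = need_conditions()
        try:
            est, composition = sensitivity_noncisgender(dataset, cond, config.z)
            sens = pd.DataFrame([_estimate_row(est)])
            _write_csv(sens, out / "sensitivity_oir.csv", files)
            _write_csv(composition, out / "gender_composition.csv", files)
        except UndefinedRateError as exc:
            notes.append(f"sensitivity skipped: {exc}")

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "created": datetime.now(timezone.utc).isoformat(),
        "cohort_flow": steps,
        "screen_stages": screen_result.stages if screen_result else None,
        "status": "partial" if notes else "success",
        "notes": notes,
        "hashes": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(files.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    files["manifest.json"] = out / "manifest.json"
    return ReportBundle(output_dir=out, manifest=manifest, files=files)
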