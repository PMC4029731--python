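"""Configured end-to-end run: cohort -> onset -> prevalence -> usage tables.

Writes publication-style CSV outputs: the attrition funnel, per-patient
onset calls and the cohort onset summary, the prevalence table with rate
ratios, the symptom-lag distributions, and diagnostic-test utilization
overall and by onset subgroup.  Fixed inputs and a fixed configuration
produce byte-identical outputs.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from als_claims.catalog import CodeCatalog, default_catalog
from als_claims.claims import quarter_of, read_claims, patients_by_id, year_quarter
from als_claims.cohort import (
    CohortCriteria,
    build_als_cohort,
    build_comparison_cohort,
    build_ttd_cohort,
)
from als_claims.onset import find_first_symptom, onset_summary
from als_claims.prevalence import (
    build_prevalence_table,
    filter_reported_rows,
    round_half_up,
)
from als_claims.usage import DEFAULT_ND_THRESHOLD, symptom_lag_distribution, test_utilization

logger = logging.getLogger("als_claims")

#: Symptoms tabulated in the lag-distribution table by default.
DEFAULT_LAG_SYMPTOMS = (
    "Muscle weakness (generalized)",
    "Gait abnormality",
    "Difficulty walking",
    "Lack of coordination",
    "Speech disturbance",
    "Voice resonance disorder",
    "Dysphagia",
)

OUTPUT_FILES = (
    "attrition.csv",
    "onset.csv",
    "onset_summary.csv",
    "prevalence.csv",
    "symptom_lags.csv",
    "test_utilization.csv",
)


@dataclass
class PipelineConfig:
    """Paths, criteria and thresholds for one pipeline run."""

    claims_path: str
    patients_path: str
    out_dir: str
    catalog_path: Optional[str] = None
    criteria: CohortCriteria = field(default_factory=CohortCriteria)
    lookback: int = 8
    comparison_window: tuple[int, int] = (quarter_of(2008, 1), quarter_of(2009, 4))
    min_prevalence: float = 10.0
    min_ratio: float = 5.0
    nd_threshold: int = DEFAULT_ND_THRESHOLD
    lag_symptoms: tuple[str, ...] = DEFAULT_LAG_SYMPTOMS
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as handle:
            payload = yaml.safe_load(handle) or {}
        criteria_payload = payload.pop("criteria", {})
        if criteria_payload:
            for key in ("diagnosis_window", "ttd_window"):
                if key in criteria_payload:
                    criteria_payload[key] = tuple(criteria_payload[key])
            payload["criteria"] = CohortCriteria(**criteria_payload)
        for key in ("comparison_window", "lag_symptoms"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _fmt(value, decimals: int = 2) -> str:
    if value is None:
        return "ND"
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        if math.isinf(value):
            return "inf"
        return f"{value:.{decimals}f}"
    return str(value)


def _write_rows(path: Path, header: Sequence[str], rows) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(header)
        writer.writerows(rows)


@dataclass
class PipelineReport:
    """In-memory results plus the paths of the written tables."""

    cohort: object
    onset_calls: dict
    summary: object
    prevalence_rows: list
    lag_rows: list
    utilization_rows: list
    paths: dict[str, Path]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    try:
        return _run(config)
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise


def _run(config: PipelineConfig) -> PipelineReport:
    catalog = (
        CodeCatalog.load(config.catalog_path) if config.catalog_path else default_catalog()
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("reading claims from %s", config.claims_path)
    patients = read_claims(config.claims_path, config.patients_path)
    by_id = patients_by_id(patients)
    logger.info("loaded %d patients", len(patients))

    # stage: cohorts
    cohort = build_als_cohort(patients, config.criteria)
    cohort = build_ttd_cohort(cohort, config.criteria)
    cohort.comparison_patients = build_comparison_cohort(patients, config.criteria)
    logger.info(
        "cohorts: ALS %d, time-to-diagnosis %d, comparison %d",
        len(cohort.als_patients),
        len(cohort.ttd_patients),
        len(cohort.comparison_patients),
    )

    # stage: onset calls on the time-to-diagnosis subcohort
    onset_calls = {
        pid: find_first_symptom(by_id[pid], catalog, dq)
        for pid, dq in sorted(cohort.ttd_patients.items())
    }
    summary = (
        onset_summary(list(onset_calls.values())) if onset_calls else None
    )
    if summary:
        logger.info(
            "onset: %d/%d classified, mix %s, median ttd %s years",
            summary.n_classified,
            summary.n_total,
            summary.proportions_pct,
            summary.median_ttd_years,
        )

    # stage: prevalence and rate ratios
    prevalence_rows = build_prevalence_table(
        cohort.als_patients,
        cohort.comparison_patients,
        by_id,
        catalog.symptom_groups(),
        onset_calls=onset_calls,
        lookback=config.lookback,
        comparison_window=config.comparison_window,
    )
    reported = filter_reported_rows(
        prevalence_rows, min_prevalence=config.min_prevalence, min_ratio=config.min_ratio
    )
    logger.info("prevalence: %d/%d rows pass the reporting filter", len(reported), len(prevalence_rows))

    # stage: lag distributions and test utilization
    lag_rows = symptom_lag_distribution(
        cohort.als_patients, by_id, catalog, config.lag_symptoms
    )
    utilization_rows = []
    for group in catalog.test_groups():
        for subgroup in (None, "limb", "bulbar", "both"):
            utilization_rows.append(
                test_utilization(
                    cohort.ttd_patients,
                    by_id,
                    group,
                    onset_calls=onset_calls,
                    lookback=config.lookback,
                    subgroup=subgroup,
                    nd_threshold=config.nd_threshold,
                )
            )

    # -- write outputs --------------------------------------------------
    paths = {name: out_dir / name for name in OUTPUT_FILES}
    _write_rows(
        paths["attrition.csv"],
        ["criterion", "label", "remaining"],
        [(i, label, count) for i, (label, count) in enumerate(cohort.attrition)],
    )
    onset_rows = []
    for pid, call in onset_calls.items():
        if call.onset_quarter is not None:
            year, quarter = year_quarter(call.onset_quarter)
        else:
            year = quarter = ""
        onset_rows.append(
            (
                pid,
                year,
                quarter,
                call.onset_category,
                _fmt(call.ttd_years),
                ";".join(sorted({code for code, _ in call.trigger})),
            )
        )
    _write_rows(
        paths["onset.csv"],
        ["patient_id", "onset_year", "onset_quarter", "category", "ttd_years", "trigger_codes"],
        onset_rows,
    )
    if summary:
        summary_rows = [
            (
                category,
                summary.proportions_pct.get(category, 0),
                summary.proportions_all_pct.get(category, 0),
                _fmt(summary.median_ttd_years_by_category.get(category)),
            )
            for category in ("limb", "bulbar", "both")
        ] + [("all", 100, "", _fmt(summary.median_ttd_years))]
    else:
        summary_rows = []
    _write_rows(
        paths["onset_summary.csv"],
        ["category", "pct_of_classified", "pct_of_cohort", "median_ttd_years"],
        summary_rows,
    )
    _write_rows(
        paths["prevalence.csv"],
        ["symptom_group", "label", "pre_als_pct", "medicare_pct", "prevalence_ratio", "median_ttd_years"],
        [
            (
                row.symptom_group,
                row.label,
                int(round_half_up(row.pre_als_pct)),
                int(round_half_up(row.medicare_pct)),
                _fmt(row.ratio.display, 1),
                _fmt(row.median_ttd_years),
            )
            for row in reported
        ],
    )
    _write_rows(
        paths["symptom_lags.csv"],
        ["symptom", "n", "mean_q", "median_q", "pct_0_3", "pct_4_7", "pct_8_11", "pct_12plus"],
        [
            (
                row.label,
                row.n,
                _fmt(row.mean_quarters),
                _fmt(row.median_quarters),
                *(_fmt(p, 1) for p in row.bin_pcts),
            )
            for row in lag_rows
        ],
    )
    _write_rows(
        paths["test_utilization.csv"],
        ["test", "cohort", "n", "n_with_test", "pct_with_test", "median_ttd_years"],
        [
            (
                row.label,
                row.subgroup or "all",
                row.n,
                row.n_with_test,
                _fmt(row.pct_with_test, 1),
                _fmt(row.median_ttd_years),
            )
            for row in utilization_rows
        ],
    )
    logger.info("wrote %d tables to %s", len(paths), out_dir)
    return PipelineReport(
        cohort=cohort,
        onset_calls=onset_calls,
        summary=summary,
        prevalence_rows=prevalence_rows,
        lag_rows=lag_rows,
        utilization_rows=utilization_rows,
        paths=paths,
    )
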