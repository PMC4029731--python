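"""Synthetic quarterly-claims generator.

Emulates the structure the analysis assumes — quarterly claim bundles,
an index ALS diagnosis code (335.20), symptom codes planted with
configurable lead times before the index event, and background code
rates in a comparison population — so every pipeline stage is testable
without access to the restricted source data.

Each ALS patient receives a diagnosis quarter drawn inside the
configured window, an onset quarter planted ``lead`` quarters earlier
(geometric lead times by default, truncated at enrollment), onset-
consistent symptom codes in the onset quarter, two index claims, and
background diagnoses at configured period-prevalence rates.  Background
patients receive per-quarter Bernoulli draws of symptom-group codes and
never carry a motor-neuron-disease code.  Planted onset quarters,
categories and lead times are returned as a ground-truth table.

By default, background symptom codes are planted in ALS patients only
for groups whose codes cannot fire the onset rule, so the planted onset
remains the ground truth the pipeline should recover;
``inject_onset_groups_in_als`` lifts that restriction to stress the
specificity of the rule.  All period-prevalence inputs ``p`` (percent
over an 8-quarter window by convention) are converted to per-quarter
Bernoulli rates ``r = 1 - (1 - p)**(1/8)`` so the planted period
prevalence matches the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from als_claims.catalog import CodeCatalog, CodeGroupDefinition, CodePattern, default_catalog
from als_claims.claims import (
    ClaimRecord,
    PatientRecord,
    SETTINGS,
    quarter_of,
    write_claims,
)

#: Comparison-population period prevalence (percent over 8 quarters) per
#: symptom group; the defaults are the reference-population column of the
#: published prevalence tables ("< 1" entries taken as 0.5).
DEFAULT_BACKGROUND_RATES_PCT: dict[str, float] = {
    "Speech disturbance": 2.0,
    "Voice resonance disorder": 1.0,
    "Muscle weakness (generalized)": 5.0,
    "Lack of coordination": 3.0,
    "Dysphagia": 7.0,
    "Hereditary and idiopathic peripheral neuropathies": 10.0,
    "Cervicalgia": 5.0,
    "Gait abnormality/difficulty walking": 11.0,
    "Transient cerebral ischemia": 5.0,
    "Loss of weight": 6.0,
    "Stroke": 4.0,
    "Lumbago/backache": 27.0,
    "Malaise and fatigue": 32.0,
    "Syncope and collapse": 14.0,
    "Pain in limb": 27.0,
    "Esophageal reflux": 21.0,
    "Constipation": 10.0,
    "Pulmonary collapse/failure": 12.0,
    "Dizziness and giddiness": 8.0,
    "Swelling in limb": 8.0,
    "Respiratory difficulties": 49.0,
    "Hypothyroidism": 22.0,
    "Nausea, vomiting, etc.": 9.0,
    "Pain in joint": 26.0,
    "Bronchitis": 14.0,
    "Chronic airway obstruction": 17.0,
    "Acute upper respiratory infection": 11.0,
    "Chronic inflammatory demyelinating polyneuropathy": 0.5,
    "Myopathy (including myopathy with weakness)": 0.5,
    "Unspecified disease of spinal cord (including myelopathy NOS)": 0.5,
    "Cervical/thoracic or lumbar spondylosis with myelopathy": 1.0,
    "Atrophy, muscular disuse": 1.0,
}

#: Pre-diagnosis period prevalence (percent over the 8-quarter lookback)
#: planted in ALS patients, from the ALS-cohort column of the published
#: prevalence tables.  Groups whose codes overlap the onset rule table
#: are skipped at generation time unless onset-group injection is on.
DEFAULT_ALS_SYMPTOM_RATES_PCT: dict[str, float] = {
    "Speech disturbance": 24.0,
    "Voice resonance disorder": 15.0,
    "Muscle weakness (generalized)": 30.0,
    "Lack of coordination": 13.0,
    "Dysphagia": 27.0,
    "Hereditary and idiopathic peripheral neuropathies": 35.0,
    "Cervicalgia": 18.0,
    "Gait abnormality/difficulty walking": 32.0,
    "Transient cerebral ischemia": 13.0,
    "Loss of weight": 17.0,
    "Stroke": 11.0,
    "Lumbago/backache": 52.0,
    "Malaise and fatigue": 56.0,
    "Syncope and collapse": 26.0,
    "Pain in limb": 44.0,
    "Esophageal reflux": 31.0,
    "Constipation": 15.0,
    "Pulmonary collapse/failure": 17.0,
    "Dizziness and giddiness": 12.0,
    "Swelling in limb": 11.0,
    "Respiratory difficulties": 62.0,
    "Hypothyroidism": 27.0,
    "Nausea, vomiting, etc.": 11.0,
    "Pain in joint": 31.0,
    "Bronchitis": 18.0,
    "Chronic airway obstruction": 19.0,
    "Acute upper respiratory infection": 12.0,
    "Chronic inflammatory demyelinating polyneuropathy": 2.0,
    "Myopathy (including myopathy with weakness)": 8.0,
    "Unspecified disease of spinal cord (including myelopathy NOS)": 5.0,
    "Cervical/thoracic or lumbar spondylosis with myelopathy": 6.0,
    "Atrophy, muscular disuse": 5.0,
}

#: Probability an ALS patient receives each diagnostic test in the
#: 8 quarters before diagnosis, by onset type; defaults follow the
#: published utilization percentages ("both" treated as limb, except for
#: the predominantly bulbar throat/upper-GI exam).
DEFAULT_TEST_PROBABILITIES: dict[str, dict[str, float]] = {
    "Sensory nerve conduction test": {"limb": 0.41, "bulbar": 0.30, "both": 0.41},
    "Motor nerve conduction test with F-wave": {"limb": 0.30, "bulbar": 0.18, "both": 0.30},
    "Motor nerve conduction test without F-wave": {"limb": 0.24, "bulbar": 0.18, "both": 0.24},
    "MRI of neck and spine without dye": {"limb": 0.29, "bulbar": 0.15, "both": 0.29},
    "CT scans (head or brain) with/without contrast material": {
        "limb": 0.43,
        "bulbar": 0.19,
        "both": 0.43,
    },
    "MRI of brain with/without dye": {"limb": 0.29, "bulbar": 0.28, "both": 0.29},
    "Limb electromyography (2 extremities and related paraspinal areas)": {
        "limb": 0.22,
        "bulbar": 0.12,
        "both": 0.22,
    },
    "Limb electromyography (1 extremity and related paraspinal areas)": {
        "limb": 0.18,
        "bulbar": 0.10,
        "both": 0.18,
    },
    "Exam of throat and/or upper gastrointestinal tract": {
        "limb": 0.15,
        "bulbar": 0.48,
        "both": 0.48,
    },
}

#: Concrete high-likelihood codes planted at the onset quarter.
ONSET_HIGH_CODES = {
    "limb": ("728.87", "719.7", "781.2", "781.3", "729.82", "728.85", "781.0", "359.1"),
    "bulbar": ("784.3", "784.51", "787.2", "527.7", "784.1", "315.39", "438.11", "784.40"),
}
#: The distinct moderate-likelihood pair used for moderate-rule limb onsets.
MODERATE_LIMB_PAIR = ("719.4", "729.5")


@dataclass
class SimulationConfig:
    """Generator settings; the defaults are the study conditions."""

    seed: int = 0
    n_als: int = 300
    n_background: int = 3000
    #: onset-type mix; renormalized (the published 74/17/8 sums to 99).
    onset_mix: dict[str, float] = field(
        default_factory=lambda: {"limb": 0.74, "bulbar": 0.17, "both": 0.08}
    )
    #: mean lead time (quarters from first symptom to diagnosis) per onset type
    lead_time_mean_quarters: dict[str, float] = field(
        default_factory=lambda: {"limb": 10.0, "bulbar": 5.0, "both": 1.0}
    )
    lead_time_model: str = "geometric"  # or "fixed"
    #: fraction of limb-onset patients planted via the two-moderate rule
    moderate_pair_fraction: float = 0.2
    background_rates_pct: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_RATES_PCT)
    )
    als_symptom_rates_pct: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ALS_SYMPTOM_RATES_PCT)
    )
    test_probabilities: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TEST_PROBABILITIES.items()}
    )
    period_quarters: int = 8
    enrollment_start: int = 0
    data_end: int = quarter_of(2009, 4)
    diagnosis_window: tuple[int, int] = (quarter_of(2008, 1), quarter_of(2009, 4))
    lookback: int = 8
    birth_year_range: tuple[int, int] = (1920, 1940)
    als_code: str = "335.20"
    inject_onset_groups_in_als: bool = False

    def validate(self) -> None:
        if self.n_als < 0 or self.n_background < 0:
            raise ValueError("population counts must be nonnegative")
        if not self.onset_mix or any(v < 0 for v in self.onset_mix.values()):
            raise ValueError("onset_mix must be nonnegative")
        if sum(self.onset_mix.values()) <= 0:
            raise ValueError("onset_mix must have positive mass")
        for rates in (self.background_rates_pct, self.als_symptom_rates_pct):
            for label, pct in rates.items():
                if not 0 <= pct <= 100:
                    raise ValueError(f"rate for {label!r} outside [0, 100]")
        if self.lead_time_model not in ("geometric", "fixed"):
            raise ValueError(f"unknown lead_time_model {self.lead_time_model!r}")
        if self.diagnosis_window[0] > self.diagnosis_window[1]:
            raise ValueError("diagnosis window must be non-empty")
        if self.diagnosis_window[1] > self.data_end:
            raise ValueError("diagnosis window extends past the end of data")
        if self.diagnosis_window[0] - self.enrollment_start < self.lookback:
            raise ValueError(
                "enrollment history shorter than the lookback window: no planted "
                "lead time can precede enrollment"
            )

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SimulationConfig":
        kwargs = dict(payload)
        for key in ("diagnosis_window", "birth_year_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def per_quarter_rate(period_pct: float, period_quarters: int = 8) -> float:
    """Per-quarter Bernoulli rate whose ``period_quarters``-quarter period
    prevalence equals ``period_pct`` percent."""
    p = period_pct / 100.0
    return 1.0 - (1.0 - p) ** (1.0 / period_quarters)


def _patterns_overlap(a: CodePattern, b: CodePattern) -> bool:
    sa, sb = a.prefix, b.prefix
    return sa.startswith(sb) or sb.startswith(sa)


def _group_touches_onset_rules(group: CodeGroupDefinition, catalog: CodeCatalog) -> bool:
    return any(
        _patterns_overlap(gp, dp)
        for gp in group.patterns
        for definition in catalog.symptom_definitions
        for dp in definition.patterns
    )


def _example_code(group: CodeGroupDefinition) -> str:
    pattern = group.patterns[0]
    if isinstance(pattern, CodePattern):
        return pattern.prefix + "1" if pattern.is_wildcard else pattern.text
    return str(pattern)


def _draw_lead(rng: np.random.Generator, config: SimulationConfig, category: str) -> int:
    mean = config.lead_time_mean_quarters[category]
    if config.lead_time_model == "fixed":
        return int(round(mean))
    # geometric on {0, 1, ...} with the requested mean
    return int(rng.geometric(1.0 / (mean + 1.0))) - 1


def _claim(pid: str, quarter: int, rng: np.random.Generator, code: str, kind: str = "diagnosis") -> ClaimRecord:
    return ClaimRecord(
        patient_id=pid,
        quarter=int(quarter),
        setting=SETTINGS[int(rng.integers(len(SETTINGS)))],
        code_kind=kind,
        code=code,
    )


def simulate_population(
    config: SimulationConfig, catalog: Optional[CodeCatalog] = None
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate (patients, ground_truth).

    The ground-truth table has one row per ALS patient with the planted
    onset category, diagnosis quarter, onset quarter and lead time
    (after truncation at enrollment).  The same seed yields the same
    population byte-for-byte.
    """
    config.validate()
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)

    categories = list(config.onset_mix)
    mix = np.array([config.onset_mix[c] for c in categories], dtype=float)
    mix /= mix.sum()

    symptom_groups = {g.label: g for g in catalog.symptom_groups()}
    test_groups = {g.label: g for g in catalog.test_groups()}
    als_injected = {
        label: pct
        for label, pct in config.als_symptom_rates_pct.items()
        if config.inject_onset_groups_in_als
        or not _group_touches_onset_rules(symptom_groups[label], catalog)
    }

    patients: list[PatientRecord] = []
    truth_rows: list[dict] = []
    width = max(4, len(str(max(config.n_als, 1))))

    for i in range(config.n_als):
        pid = f"als-{i:0{width}d}"
        dq = int(rng.integers(config.diagnosis_window[0], config.diagnosis_window[1] + 1))
        category = categories[int(rng.choice(len(categories), p=mix))]
        lead = _draw_lead(rng, config, category)
        onset_q = max(config.enrollment_start, dq - lead)
        lead = dq - onset_q

        claims: list[ClaimRecord] = []
        # onset-consistent symptom codes in the onset quarter
        onset_codes: list[str]
        if category == "both":
            onset_codes = [
                str(rng.choice(ONSET_HIGH_CODES["limb"])),
                str(rng.choice(ONSET_HIGH_CODES["bulbar"])),
            ]
        elif category == "limb" and rng.random() < config.moderate_pair_fraction:
            onset_codes = list(MODERATE_LIMB_PAIR)
        else:
            onset_codes = [str(rng.choice(ONSET_HIGH_CODES[category]))]
        for code in onset_codes:
            claims.append(_claim(pid, onset_q, rng, code))

        # two index claims; the second stays inside the data span
        claims.append(_claim(pid, dq, rng, config.als_code))
        claims.append(_claim(pid, min(dq + 1, config.data_end), rng, config.als_code))

        # background symptom burden in the pre-diagnosis lookback window
        window = range(max(config.enrollment_start, dq - config.lookback), dq)
        for label in als_injected:
            rate = per_quarter_rate(als_injected[label], config.period_quarters)
            code = _example_code(symptom_groups[label])
            for quarter in window:
                if rng.random() < rate:
                    claims.append(_claim(pid, quarter, rng, code))

        # diagnostic tests in the lookback window
        for label, probs in config.test_probabilities.items():
            if rng.random() < probs.get(category, 0.0):
                quarter = int(rng.integers(max(config.enrollment_start, dq - config.lookback), dq))
                claims.append(
                    _claim(pid, quarter, rng, _example_code(test_groups[label]), "procedure_group")
                )

        claims.sort(key=lambda c: (c.quarter, c.code_kind, c.code, c.setting))
        patients.append(
            PatientRecord(
                patient_id=pid,
                birth_year=int(rng.integers(config.birth_year_range[0], config.birth_year_range[1] + 1)),
                enrollment_start=config.enrollment_start,
                in_physician_office_sample=True,
                claims=claims,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "category": category,
                "diagnosis_quarter": dq,
                "onset_quarter": onset_q,
                "lead_quarters": lead,
                "onset_codes": ";".join(onset_codes),
            }
        )

    # background (comparison) population: vectorized per-group Bernoulli draws
    n_quarters = config.data_end - config.enrollment_start + 1
    bg_width = max(5, len(str(max(config.n_background, 1))))
    bg_claims: dict[int, list[ClaimRecord]] = {j: [] for j in range(config.n_background)}
    if config.n_background:
        for label in config.background_rates_pct:
            group = symptom_groups[label]
            rate = per_quarter_rate(config.background_rates_pct[label], config.period_quarters)
            hits = rng.random((config.n_background, n_quarters)) < rate
            code = _example_code(group)
            for j, offset in zip(*np.nonzero(hits)):
                pid = f"bg-{j:0{bg_width}d}"
                bg_claims[int(j)].append(
                    _claim(pid, config.enrollment_start + int(offset), rng, code)
                )
        birth_years = rng.integers(
            config.birth_year_range[0], config.birth_year_range[1] + 1, size=config.n_background
        )
        for j in range(config.n_background):
            claims = sorted(bg_claims[j], key=lambda c: (c.quarter, c.code_kind, c.code, c.setting))
            patients.append(
                PatientRecord(
                    patient_id=f"bg-{j:0{bg_width}d}",
                    birth_year=int(birth_years[j]),
                    enrollment_start=config.enrollment_start,
                    in_physician_office_sample=True,
                    claims=claims,
                )
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id",
            "category",
            "diagnosis_quarter",
            "onset_quarter",
            "lead_quarters",
            "onset_codes",
        ],
    )
    return patients, truth


def write_fixture(
    patients: Sequence[PatientRecord], truth: pd.DataFrame, out_dir
) -> dict[str, Path]:
    """Write claims.csv, patients.csv and truth.csv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "claims": out / "claims.csv",
        "patients": out / "patients.csv",
        "truth": out / "truth.csv",
    }
    write_claims(patients, paths["claims"], paths["patients"])
    truth.to_csv(paths["truth"], index=False)
    return paths
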