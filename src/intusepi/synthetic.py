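"""Seeded synthetic hospital registry and admission-record generator.

Emulates a six-month extract of a partial-coverage national inpatient
claims database: a national registry of acute-care hospitals spanning four
bed-volume classes, with a configurable bed-share participating in the
database, and admission records (intussusception cases plus all-cause
background admissions) generated for the participating hospitals only —
non-participating hospitals contribute beds to the national denominators
but no records, exactly as in the real database.

One global integer seed drives independent named sub-streams (hospitals,
cases, background) through ``numpy.random.SeedSequence(entropy=seed,
spawn_key=(k,))``, so regenerating one table never perturbs another.
"""

from __future__ import annotations

import importlib.resources
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .types import (
    ADMISSION_COLUMNS,
    HOSPITAL_COLUMNS,
    ConfigurationError,
    GeneratorConfig,
    ValidationError,
)

_STREAM_HOSPITALS = 0
_STREAM_CASES = 1
_STREAM_BACKGROUND = 2

#: Diagnosis codes drawn for all-cause background admissions (common
#: paediatric inpatient diagnoses; none match the intussusception prefix).
_BACKGROUND_CODES = ("J18.9", "A08.0", "J21.9", "A09", "N10", "S06.0", "J45.9", "K35.8")


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


def load_lead_point_vocabulary() -> pd.DataFrame:
    """The pathological-lead-point vocabulary (cause, group, frequency)."""
    ref = importlib.resources.files("intusepi.data").joinpath("lead_points.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def generate_hospitals(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a national hospital registry with participation flags.

    Bed counts are drawn from the configured volume-class mixture (uniform
    within each class range). Participation is assigned within each volume
    class by a random greedy fill until the class's participating bed share
    reaches ``coverage_fraction``, so both the overall and the per-class
    coverage track the configured value.
    """
    config.validate()
    n = config.n_hospitals
    if n == 0:
        return pd.DataFrame(columns=HOSPITAL_COLUMNS).astype(
            {"beds": int, "participates": bool}
        )
    rng = _rng(config, _STREAM_HOSPITALS)
    weights = np.array([c.weight for c in config.bed_classes])
    cls = rng.choice(len(config.bed_classes), size=n, p=weights)
    lows = np.array([c.low_beds for c in config.bed_classes])
    highs = np.array([c.high_beds for c in config.bed_classes])
    beds = rng.integers(lows[cls], highs[cls] + 1)

    participates = np.zeros(n, dtype=bool)
    for k in range(len(config.bed_classes)):
        idx = np.flatnonzero(cls == k)
        if idx.size == 0:
            continue
        order = rng.permutation(idx)
        target = config.coverage_fraction * beds[idx].sum()
        cum = 0
        for i in order:
            # every non-empty class keeps >= 1 participant (the database
            # covers all volume classes); after that, add the next hospital
            # only while it brings the class's bed share closer to target
            if cum > 0 and abs(cum + beds[i] - target) >= abs(cum - target):
                break
            participates[i] = True
            cum += beds[i]

    return pd.DataFrame(
        {
            "hospital_id": [f"H{i:05d}" for i in range(n)],
            "beds": beds.astype(int),
            "participates": participates,
        }
    )


def _sample_age_months(rng: np.random.Generator, size: int, config: GeneratorConfig) -> np.ndarray:
    """Age-at-admission mixture for intussusception cases.

    A shifted gamma (mode near 8-10 months, median near 17 months,
    truncated below 60 months) carries ``age_young_weight`` of the mass;
    the remainder is uniform over 60-227 months, giving the thin tail to
    18 years seen in hospital series.
    """
    young = rng.random(size) < config.age_young_weight
    n_young = int(young.sum())
    ages = np.empty(size)
    draw = config.age_shift_months + rng.gamma(
        config.age_gamma_shape, config.age_gamma_scale_months, size=n_young
    )
    while True:  # truncate the bulk below 5 years by resampling
        bad = draw >= 60
        if not bad.any():
            break
        draw[bad] = config.age_shift_months + rng.gamma(
            config.age_gamma_shape, config.age_gamma_scale_months, size=int(bad.sum())
        )
    ages[young] = draw
    ages[~young] = rng.integers(60, 228, size=size - n_young)
    return np.floor(ages).astype(int)


def _secondary_prob(ages_months: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Per-record lead-point probability looked up by Table-2 age bin."""
    years = ages_months // 12
    bounds = {"0": (0, 0), "1": (1, 1), "2": (2, 2), "3-4": (3, 4), "5-12": (5, 12), "13-18": (13, 18)}
    out = np.zeros(len(ages_months))
    for label, p in config.secondary_prob_by_age:
        lo, hi = bounds[label]
        out[(years >= lo) & (years <= hi)] = p
    return out


def generate_admissions(hospitals: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Generate the admission-record table for participating hospitals.

    Intussusception case counts per hospital are Poisson with mean
    ``beds × case_rate_per_bed × period_days``; all-cause background
    admissions likewise with ``background_rate_per_bed``. A configured
    fraction of cases is re-emitted as a same-hospital readmission within
    ``readmission_gap_days`` (gap 1 + Poisson(1.3), mean ≈ 2.3 days),
    always as a new independent record.
    """
    config.validate()
    if len(hospitals) == 0:
        if config.case_rate_per_bed > 0 or config.background_rate_per_bed > 0:
            raise ValidationError("non-zero admission rates require a non-empty registry")
        return _empty_admissions()
    if hospitals["hospital_id"].duplicated().any():
        raise ValidationError("hospital_id not unique in registry")

    part = hospitals.loc[hospitals["participates"]]
    days = config.period_days
    frames = []

    rng = _rng(config, _STREAM_CASES)
    n_cases = rng.poisson(part["beds"].to_numpy() * config.case_rate_per_bed * days)
    frames.append(_make_cases(part, n_cases, rng, config))

    rng_bg = _rng(config, _STREAM_BACKGROUND)
    n_bg = rng_bg.poisson(part["beds"].to_numpy() * config.background_rate_per_bed * days)
    frames.append(_make_background(part, n_bg, rng_bg, config))

    frames = [f for f in frames if len(f)]
    if not frames:
        return _empty_admissions()
    out = pd.concat(frames, ignore_index=True)
    return out[list(ADMISSION_COLUMNS)]


def _empty_admissions() -> pd.DataFrame:
    return pd.DataFrame(columns=ADMISSION_COLUMNS)


def _random_dates(rng: np.random.Generator, size: int, config: GeneratorConfig) -> np.ndarray:
    offsets = rng.integers(0, config.period_days, size=size)
    start = config.period_start
    return np.array([start + timedelta(days=int(o)) for o in offsets], dtype=object)


def _make_cases(
    part: pd.DataFrame, n_per_hospital: np.ndarray, rng: np.random.Generator, config: GeneratorConfig
) -> pd.DataFrame:
    total = int(n_per_hospital.sum())
    if total == 0:
        return _empty_admissions()
    hosp_ids = np.repeat(part["hospital_id"].to_numpy(), n_per_hospital)
    ages = _sample_age_months(rng, total, config)
    sex = np.where(rng.random(total) < config.sex_ratio_male, "male", "female")

    surgery = rng.random(total) >= config.enema_success_prob
    resect = surgery & (rng.random(total) < config.resection_given_surgery_prob)
    treatment = np.where(resect, "surgery_with_resection", np.where(surgery, "surgery", "enema_success"))

    died = rng.random(total) < config.death_prob
    level1 = rng.random(total) < config.level1_evidence_prob
    evidence = np.where(surgery, "surgical", "radiological")
    evidence = np.where(died & ~surgery, "autopsy", evidence)
    evidence = np.where(level1, evidence, "none")

    vocab = load_lead_point_vocabulary()
    is_secondary = rng.random(total) < _secondary_prob(ages, config)
    causes = np.full(total, None, dtype=object)
    n_sec = int(is_secondary.sum())
    if n_sec:
        w = vocab["patients"].to_numpy() / vocab["patients"].sum()
        causes[is_secondary] = rng.choice(vocab["cause"].to_numpy(), size=n_sec, p=w)

    has_comp = rng.random(total) < config.complication_prob
    comp_kinds = np.array(["perforation_peritonitis", "systemic_infection", "shock", "seizure"])
    comp = np.full(total, "none", dtype=object)
    n_comp = int(has_comp.sum())
    if n_comp:
        comp[has_comp] = rng.choice(comp_kinds, size=n_comp, p=np.array([9, 8, 5, 3]) / 25)

    admit = _random_dates(rng, total, config)
    los = np.where(surgery, 1 + rng.poisson(7.3, total), 1 + rng.poisson(2.5, total))
    discharge = np.array(
        [min(a + timedelta(days=int(l)), config.period_end) for a, l in zip(admit, los)],
        dtype=object,
    )

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(total)],
            "hospital_id": hosp_ids,
            "age_months": ages,
            "sex": sex,
            "admit_date": admit,
            "discharge_date": discharge,
            "icd10_codes": "K56.1",
            "brighton_evidence": evidence,
            "treatment": treatment,
            "secondary_cause": causes,
            "complication": comp,
            "died": died,
        }
    )

    # Same-hospital readmissions: new independent rows, never merged.
    readmit = (rng.random(total) < config.readmission_prob) & ~died
    gaps = np.minimum(1 + rng.poisson(1.3, total), config.readmission_gap_days)
    re_rows = []
    for i in np.flatnonzero(readmit):
        r_admit = discharge[i] + timedelta(days=int(gaps[i]))
        r_dis = r_admit + timedelta(days=int(1 + rng.poisson(2.5)))
        if r_dis > config.period_end:
            continue
        row = df.iloc[i].copy()
        row["admit_date"] = r_admit
        row["discharge_date"] = r_dis
        row["treatment"] = "enema_success" if rng.random() < config.enema_success_prob else "surgery"
        row["brighton_evidence"] = "radiological" if row["treatment"] == "enema_success" else "surgical"
        row["complication"] = "none"
        row["died"] = False
        re_rows.append(row)
    if re_rows:
        df = pd.concat([df, pd.DataFrame(re_rows)], ignore_index=True)
    return df


def _make_background(
    part: pd.DataFrame, n_per_hospital: np.ndarray, rng: np.random.Generator, config: GeneratorConfig
) -> pd.DataFrame:
    total = int(n_per_hospital.sum())
    if total == 0:
        return _empty_admissions()
    hosp_ids = np.repeat(part["hospital_id"].to_numpy(), n_per_hospital)
    # All-cause paediatric age profile: bin weights from the study's
    # admission margins, uniform in months within each bin.
    bin_bounds = [(0, 11), (12, 23), (24, 35), (36, 59), (60, 155), (156, 227)]
    bin_weights = np.array([157494, 88125, 51900, 74689, 157099, 97463], dtype=float)
    bin_weights /= bin_weights.sum()
    which = rng.choice(len(bin_bounds), size=total, p=bin_weights)
    lo = np.array([b[0] for b in bin_bounds])[which]
    hi = np.array([b[1] for b in bin_bounds])[which]
    ages = rng.integers(lo, hi + 1)

    admit = _random_dates(rng, total, config)
    los = 1 + rng.poisson(3.0, total)
    discharge = np.array(
        [min(a + timedelta(days=int(l)), config.period_end) for a, l in zip(admit, los)],
        dtype=object,
    )
    return pd.DataFrame(
        {
            "patient_id": [f"B{i:06d}" for i in range(total)],
            "hospital_id": hosp_ids,
            "age_months": ages.astype(int),
            "sex": np.where(rng.random(total) < 0.5, "male", "female"),
            "admit_date": admit,
            "discharge_date": discharge,
            "icd10_codes": rng.choice(np.array(_BACKGROUND_CODES), size=total),
            "brighton_evidence": "none",
            "treatment": "none",
            "secondary_cause": None,
            "complication": "none",
            "died": False,
        }
    )


def check_referential_integrity(admissions: pd.DataFrame, hospitals: pd.DataFrame) -> None:
    """Raise if any admission references a hospital absent from the registry."""
    known = set(hospitals["hospital_id"])
    missing = set(admissions["hospital_id"]) - known
    if missing:
        raise ValidationError(f"admissions reference unknown hospitals: {sorted(missing)[:5]}")


def write_tables(
    hospitals: pd.DataFrame, admissions: pd.DataFrame, hospitals_path, admissions_path
) -> None:
    """Write the two tables as UTF-8 RFC-4180 CSV with ISO-8601 dates."""
    hospitals.to_csv(hospitals_path, index=False)
    admissions.to_csv(admissions_path, index=False)


def read_hospitals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["participates"] = df["participates"].astype(bool)
    return df


def read_admissions(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    if len(df) == 0:
        return _empty_admissions()
    for col in ("admit_date", "discharge_date"):
        df[col] = pd.to_datetime(df[col]).dt.date
    df["died"] = df["died"].astype(bool)
    df["secondary_cause"] = df["secondary_cause"].where(df["secondary_cause"].notna(), None)
    return df
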