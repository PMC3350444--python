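"""Core domain types shared across the pipeline.

Record-level data (hospital registries, admission episodes) travels as
:class:`pandas.DataFrame` objects with the column schemas declared here;
configuration and results are small frozen dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional

SEX_LEVELS = ("male", "female")
BRIGHTON_LEVELS = ("surgical", "radiological", "autopsy", "none")
TREATMENT_LEVELS = ("enema_success", "surgery", "surgery_with_resection", "none")
COMPLICATION_LEVELS = (
    "perforation_peritonitis",
    "systemic_infection",
    "shock",
    "seizure",
    "none",
)

#: Column schema of a hospital registry table.
HOSPITAL_COLUMNS = ("hospital_id", "beds", "participates")

#: Column schema of an admission-record table.
ADMISSION_COLUMNS = (
    "patient_id",
    "hospital_id",
    "age_months",
    "sex",
    "admit_date",
    "discharge_date",
    "icd10_codes",
    "brighton_evidence",
    "treatment",
    "secondary_cause",
    "complication",
    "died",
)


class ConfigurationError(ValueError):
    """A generator or pipeline configuration violates its invariants."""


class ValidationError(ValueError):
    """An input record or argument violates a precondition."""


@dataclass(frozen=True)
class StratumDefinition:
    """A hospital bed-volume stratum, a half-open interval [lower, upper).

    ``upper is None`` means unbounded above. The default four strata are
    <400, 400-<600, 600-<800 and >=800 beds; exactly 800 beds falls in the
    top stratum.
    """

    index: int
    lower_beds: int
    upper_beds: Optional[int]

    def contains(self, beds: int) -> bool:
        if beds < self.lower_beds:
            return False
        return self.upper_beds is None or beds < self.upper_beds

    @property
    def label(self) -> str:
        if self.upper_beds is None:
            return f">= {self.lower_beds} beds"
        if self.lower_beds <= 1:
            return f"< {self.upper_beds} beds"
        return f"{self.lower_beds} - < {self.upper_beds} beds"


DEFAULT_STRATA: tuple[StratumDefinition, ...] = (
    StratumDefinition(1, 1, 400),
    StratumDefinition(2, 400, 600),
    StratumDefinition(3, 600, 800),
    StratumDefinition(4, 800, None),
)


@dataclass(frozen=True)
class StratumCounts:
    """Inputs of the scale-up estimator for one stratum.

    ``national_beds`` (N_i) is the stratum's bed total over all acute-care
    hospitals; ``db_beds`` (n_i) the beds in database-participating
    hospitals; ``cases`` (X_i) the observed cases in the collection window.
    """

    stratum: StratumDefinition
    national_beds: int
    db_beds: int
    cases: int

    def __post_init__(self) -> None:
        if not (0 < self.db_beds <= self.national_beds):
            raise ValidationError(
                f"stratum {self.stratum.index}: need 0 < n_i <= N_i, got "
                f"n_i={self.db_beds}, N_i={self.national_beds}"
            )
        if self.cases < 0:
            raise ValidationError(f"stratum {self.stratum.index}: negative case count")


@dataclass(frozen=True)
class StratumEstimate:
    """Annualized national case estimate for one stratum with a Wald CI."""

    stratum: StratumDefinition
    cases_per_bed: float  # annualized per-bed proportion p
    estimate: float  # Y_i, unrounded
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class NationalEstimate:
    """National annual case total, CI, and birth-cohort incidence."""

    total: int
    ci_low: int
    ci_high: int
    incidence_per_100k: float
    incidence_ci: tuple[float, float]
    births_denominator: int
    total_unrounded: float = 0.0


@dataclass(frozen=True)
class ExactBinomialCI:
    """Clopper-Pearson exact interval for a binomial proportion."""

    successes: int
    trials: int
    level: float
    low: float
    high: float

    @property
    def proportion(self) -> float:
        return self.successes / self.trials


@dataclass(frozen=True)
class ScreenCriteria:
    """Inclusion rules for analyzable intussusception cases.

    Cases must carry a diagnosis code starting with ``icd10_prefix`` (after
    dot-stripping), be at most ``max_age_years`` completed years old at
    admission, and have diagnostic confirmation in ``required_brighton``
    (level-1 certainty: surgical, radiological or autopsy evidence).
    """

    icd10_prefix: str = "K561"
    max_age_years: int = 18
    required_brighton: frozenset[str] = frozenset({"surgical", "radiological", "autopsy"})
    readmission_window_days: int = 7

    def __post_init__(self) -> None:
        if self.max_age_years < 0:
            raise ConfigurationError("max_age_years must be >= 0")
        if not self.required_brighton:
            raise ConfigurationError("required_brighton must be non-empty")


@dataclass(frozen=True)
class AgeBin:
    """An age group in completed years, inclusive bounds."""

    label: str
    lower_years: int
    upper_years: int

    def contains_months(self, age_months: int) -> bool:
        years = age_months // 12
        return self.lower_years <= years <= self.upper_years


DEFAULT_AGE_BINS: tuple[AgeBin, ...] = (
    AgeBin("0", 0, 0),
    AgeBin("1", 1, 1),
    AgeBin("2", 2, 2),
    AgeBin("3-4", 3, 4),
    AgeBin("5-12", 5, 12),
    AgeBin("13-18", 13, 18),
)


@dataclass(frozen=True)
class BedClass:
    """One mixture component of the bed-count distribution: a volume class
    with a sampling weight and a uniform bed range [low, high]."""

    weight: float
    low_beds: int
    high_beds: int


# Class weights follow the national hospital counts by volume class
# (7,001 / 466 / 161 / 95 of 7,723 acute-care hospitals). The <400-bed
# class is split into a small-hospital bulk and a mid-size component so the
# registry-wide mean bed count matches the national ~118 beds/hospital.
DEFAULT_BED_CLASSES: tuple[BedClass, ...] = (
    BedClass(0.8500, 20, 100),
    BedClass(7001 / 7723 - 0.8500, 100, 399),
    BedClass(466 / 7723, 400, 599),
    BedClass(161 / 7723, 600, 799),
    BedClass(95 / 7723, 800, 1200),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic claims-database generator.

    Defaults emulate the study conditions: a six-month (July-December)
    extract of a ~45%-coverage national inpatient database, with case
    marginals set to the printed ratios (male 1610/2427, enema success
    2255/2427, resection 52/175 of surgical, complications 27/2427, deaths
    2/2427, same-hospital readmissions 37/2427). The registry defaults to a
    1:10 scale of the ~7,700-hospital national registry.
    """

    seed: int = 0
    n_hospitals: int = 772
    bed_classes: tuple[BedClass, ...] = DEFAULT_BED_CLASSES
    coverage_fraction: float = 0.45
    period_start: date = date(2007, 7, 1)
    period_end: date = date(2007, 12, 31)
    case_rate_per_bed: float = 1.9e-5  # intussusception cases / bed / day
    background_rate_per_bed: float = 4.8e-3  # all-cause paediatric admissions / bed / day
    sex_ratio_male: float = 1610 / 2427
    level1_evidence_prob: float = 0.9
    enema_success_prob: float = 2255 / 2427
    resection_given_surgery_prob: float = 52 / 175
    # Secondary (lead-point) probability by Table-2 age bin label.
    secondary_prob_by_age: tuple[tuple[str, float], ...] = (
        ("0", 0.016),
        ("1", 0.012),
        ("2", 0.029),
        ("3-4", 0.023),
        ("5-12", 0.149),
        ("13-18", 0.371),
    )
    complication_prob: float = 27 / 2427
    death_prob: float = 2 / 2427
    readmission_prob: float = 37 / 2427
    readmission_gap_days: int = 7
    # Age mixture: shifted-gamma bulk under 5 years + uniform tail to 18 y.
    age_young_weight: float = 0.925
    age_gamma_shape: float = 2.0
    age_gamma_scale_months: float = 7.5
    age_shift_months: float = 2.0

    def validate(self) -> None:
        if self.n_hospitals < 0:
            raise ConfigurationError("n_hospitals must be >= 0")
        if self.period_end < self.period_start:
            raise ConfigurationError("period must span >= 1 day")
        if self.case_rate_per_bed < 0 or self.background_rate_per_bed < 0:
            raise ConfigurationError("rates must be non-negative")
        probs = {
            "coverage_fraction": self.coverage_fraction,
            "sex_ratio_male": self.sex_ratio_male,
            "level1_evidence_prob": self.level1_evidence_prob,
            "enema_success_prob": self.enema_success_prob,
            "resection_given_surgery_prob": self.resection_given_surgery_prob,
            "complication_prob": self.complication_prob,
            "death_prob": self.death_prob,
            "readmission_prob": self.readmission_prob,
            "age_young_weight": self.age_young_weight,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        for label, p in self.secondary_prob_by_age:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"secondary_prob_by_age[{label}] outside [0, 1]")
        if not self.coverage_fraction > 0:
            raise ConfigurationError("coverage_fraction must be in (0, 1]")
        total_w = sum(c.weight for c in self.bed_classes)
        if abs(total_w - 1.0) > 1e-9:
            raise ConfigurationError("bed class weights must sum to 1")
        for c in self.bed_classes:
            if c.low_beds < 1 or c.high_beds < c.low_beds:
                raise ConfigurationError("bed class range invalid")

    @property
    def period_days(self) -> int:
        return (self.period_end - self.period_start).days + 1
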