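"""Descriptive epidemiology of screened intussusception cases.

Age-specific admission rates (cases per 1,000 all-cause admissions by age
group), demographic summaries (sex, median age and IQR, under-5 and infant
fractions), treatment outcomes (enema success, surgery, bowel resection),
length-of-stay medians by treatment arm, pathological-lead-point
tabulation, complication counts, and case fatality with an exact binomial
confidence interval.

Percentages and rates are reported half-up at one decimal by default
(configurable), medians and IQRs use linear interpolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .incidence import exact_binomial_ci
from .synthetic import load_lead_point_vocabulary
from .types import DEFAULT_AGE_BINS, AgeBin, ExactBinomialCI, ValidationError

logger = logging.getLogger(__name__)

LEAD_POINT_GROUPS = ("Structural", "Vascular/hematological", "Neoplasms", "Others")


def round_half_up(x: float, decimals: int = 1) -> float:
    scale = 10.0**decimals
    return math.floor(x * scale + 0.5) / scale


def percentage(part: int, whole: int, decimals: Optional[int] = 1) -> float:
    """100 × part/whole, reported half-up at ``decimals`` (None = exact)."""
    if whole <= 0:
        raise ValidationError("percentage denominator must be > 0")
    value = 100.0 * part / whole
    return value if decimals is None else round_half_up(value, decimals)


def rate_per_1000_admissions(
    cases: int, admissions: int, decimals: Optional[int] = 1
) -> float:
    """Cases per 1,000 all-cause admissions, reported half-up at 1 dp."""
    if admissions <= 0:
        raise ValidationError("rate undefined: zero all-cause admissions")
    value = 1000.0 * cases / admissions
    return value if decimals is None else round_half_up(value, decimals)


def age_rate_table(
    admissions: pd.DataFrame,
    cases: pd.DataFrame,
    bins: Sequence[AgeBin] = DEFAULT_AGE_BINS,
) -> pd.DataFrame:
    """Per-age-group admission counts, case rates and secondary fractions.

    The analogue of the study's age table: for each bin, all-cause
    admissions, intussusception cases, cases per 1,000 admissions, and
    lead-point (secondary) cases with their share of the bin's cases.
    """
    rows = []
    for b in bins:
        in_bin_adm = admissions["age_months"].floordiv(12).between(b.lower_years, b.upper_years)
        in_bin_case = cases["age_months"].floordiv(12).between(b.lower_years, b.upper_years)
        n_adm = int(in_bin_adm.sum())
        n_case = int(in_bin_case.sum())
        n_sec = int(cases.loc[in_bin_case, "secondary_cause"].notna().sum()) if n_case else 0
        rows.append(
            {
                "age_bin": b.label,
                "all_cause_admissions": n_adm,
                "intussusceptions": n_case,
                "per_1000_admissions": rate_per_1000_admissions(n_case, n_adm) if n_adm else float("nan"),
                "secondary_cases": n_sec,
                "secondary_pct": percentage(n_sec, n_case) if n_case else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CaseSummary:
    """Overall descriptive summary of a screened case series.

    Medians are ``None`` when the series is empty (explicit sentinel).
    """

    n_cases: int
    n_male: int
    male_pct: float
    median_age_months: Optional[float]
    age_iqr_months: Optional[tuple[float, float]]
    n_under_5: int
    under_5_pct: float
    n_infants: int
    infant_pct: float
    n_enema_success: int
    enema_success_pct: float
    n_surgical: int
    n_resection: int
    resection_pct_of_surgical: float
    los_median_nonsurgical: Optional[float]
    los_median_surgical: Optional[float]
    n_secondary: int
    secondary_pct: float
    complication_counts: Mapping[str, int]
    n_complications: int
    complication_pct: float
    n_deaths: int
    case_fatality: Optional[ExactBinomialCI]


def summarize_cases(
    cases: pd.DataFrame, bins: Sequence[AgeBin] = DEFAULT_AGE_BINS
) -> CaseSummary:
    """Compute the overall descriptive summary from screened case records."""
    n = len(cases)
    if n == 0:
        return CaseSummary(
            n_cases=0, n_male=0, male_pct=float("nan"),
            median_age_months=None, age_iqr_months=None,
            n_under_5=0, under_5_pct=float("nan"),
            n_infants=0, infant_pct=float("nan"),
            n_enema_success=0, enema_success_pct=float("nan"),
            n_surgical=0, n_resection=0, resection_pct_of_surgical=float("nan"),
            los_median_nonsurgical=None, los_median_surgical=None,
            n_secondary=0, secondary_pct=float("nan"),
            complication_counts={}, n_complications=0, complication_pct=float("nan"),
            n_deaths=0, case_fatality=None,
        )

    ages = cases["age_months"].to_numpy()
    n_male = int((cases["sex"] == "male").sum())
    n_under5 = int((ages < 60).sum())
    n_inf = int((ages < 12).sum())
    surgical_mask = cases["treatment"].isin(["surgery", "surgery_with_resection"])
    n_surg = int(surgical_mask.sum())
    n_res = int((cases["treatment"] == "surgery_with_resection").sum())
    n_enema = int((cases["treatment"] == "enema_success").sum())
    n_sec = int(cases["secondary_cause"].notna().sum())
    comp = cases["complication"].fillna("none")
    comp_counts = comp[comp != "none"].value_counts().to_dict()
    n_comp = int(sum(comp_counts.values()))
    n_deaths = int(cases["died"].sum())

    los = (pd.to_datetime(cases["discharge_date"]) - pd.to_datetime(cases["admit_date"])).dt.days
    los_ns = los[~surgical_mask]
    los_s = los[surgical_mask]

    return CaseSummary(
        n_cases=n,
        n_male=n_male,
        male_pct=percentage(n_male, n),
        median_age_months=float(np.median(ages)),
        age_iqr_months=(float(np.percentile(ages, 25)), float(np.percentile(ages, 75))),
        n_under_5=n_under5,
        under_5_pct=percentage(n_under5, n),
        n_infants=n_inf,
        infant_pct=percentage(n_inf, n),
        n_enema_success=n_enema,
        enema_success_pct=percentage(n_enema, n),
        n_surgical=n_surg,
        n_resection=n_res,
        resection_pct_of_surgical=percentage(n_res, n_surg) if n_surg else float("nan"),
        los_median_nonsurgical=float(los_ns.median()) if len(los_ns) else None,
        los_median_surgical=float(los_s.median()) if len(los_s) else None,
        n_secondary=n_sec,
        secondary_pct=percentage(n_sec, n),
        complication_counts=comp_counts,
        n_complications=n_comp,
        complication_pct=percentage(n_comp, n),
        n_deaths=n_deaths,
        case_fatality=exact_binomial_ci(n_deaths, n),
    )


def tabulate_lead_points(cases: pd.DataFrame) -> pd.DataFrame:
    """Tabulate pathological lead points by cause within four groups.

    Returns one row per observed cause: group, cause, patient count, and
    the age range in completed years. Causes absent from the standard
    vocabulary are retained under an "Unclassified" group with a warning.
    """
    sec = cases.loc[cases["secondary_cause"].notna()]
    if len(sec) == 0:
        return pd.DataFrame(columns=["group", "cause", "patients", "age_min_years", "age_max_years"])
    vocab = load_lead_point_vocabulary().set_index("cause")["group"]
    rows = []
    for cause, grp in sec.groupby("secondary_cause", sort=False):
        if cause in vocab.index:
            group = vocab[cause]
        else:
            logger.warning("unknown lead-point label %r; grouped as Unclassified", cause)
            group = "Unclassified"
        years = grp["age_months"].floordiv(12)
        rows.append(
            {
                "group": group,
                "cause": cause,
                "patients": len(grp),
                "age_min_years": int(years.min()),
                "age_max_years": int(years.max()),
            }
        )
    order = {g: i for i, g in enumerate(LEAD_POINT_GROUPS + ("Unclassified",))}
    out = pd.DataFrame(rows)
    return out.sort_values(["group", "cause"], key=lambda s: s.map(lambda v: order.get(v, v))
                           if s.name == "group" else s, kind="stable").reset_index(drop=True)


def summarize_complications(
    cases: pd.DataFrame,
) -> tuple[dict[str, int], Optional[ExactBinomialCI]]:
    """Complication counts by category plus case fatality with an exact CI."""
    comp = cases["complication"].fillna("none") if len(cases) else pd.Series(dtype=object)
    counts = {
        k: int((comp == k).sum())
        for k in ("perforation_peritonitis", "systemic_infection", "shock", "seizure")
    }
    if len(cases) == 0:
        return counts, None
    return counts, exact_binomial_ci(int(cases["died"].sum()), len(cases))
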