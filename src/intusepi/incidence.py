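"""Stratified national scale-up estimation of annual intussusception cases.

The estimator treats hospital beds as the sampling frame. Within each
bed-volume stratum i, the annualized per-bed case proportion is

    p_i = a * X_i / n_i

where X_i is the case count observed in participating hospitals during the
collection window, n_i the participating beds, and a the annualization
factor (2 for a six-month window under a no-seasonality assumption). The
national annual estimate and its Wald interval are

    Y_i = p_i * N_i,    CI_i = N_i * (p_i ± z * sqrt(p_i (1 - p_i) / n_i))

with N_i the stratum's national bed total and z fixed at 1.96. No
finite-population correction is applied even though n_i/N_i is large; the
plain binomial variance is deliberate. Bounds are clamped to [0, N_i].

Reporting convention: per-stratum values are rounded half-up; the national
total is the truncation toward zero of the *unrounded* stratum sum; the
national CI bounds are sums of the rounded per-stratum bounds. Birth-cohort
incidence divides the total by an annual birth count (default 1,090,000)
per 100,000 infants.

Exact binomial ("Fisher's exact") confidence intervals for case proportions
are Clopper-Pearson, delegated to statsmodels.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .types import (
    DEFAULT_STRATA,
    ExactBinomialCI,
    NationalEstimate,
    StratumCounts,
    StratumDefinition,
    StratumEstimate,
    ValidationError,
)

DEFAULT_BIRTHS = 1_090_000
DEFAULT_Z = 1.96
DEFAULT_ANNUALIZATION = 2.0


class EstimationError(ValueError):
    """The estimator's inputs are implausible (e.g. per-bed proportion > 1)."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero toward +inf."""
    return math.floor(x + 0.5)


def assign_stratum(
    beds: int, strata: Sequence[StratumDefinition] = DEFAULT_STRATA
) -> StratumDefinition:
    """Map a bed count to its (unique) volume stratum."""
    if beds < 1:
        raise ValidationError(f"beds must be >= 1, got {beds}")
    for s in strata:
        if s.contains(beds):
            return s
    raise ValidationError(f"no stratum covers {beds} beds")


def tabulate_strata(
    cases: pd.DataFrame,
    hospitals: pd.DataFrame,
    national_beds: Mapping[int, int],
    strata: Sequence[StratumDefinition] = DEFAULT_STRATA,
) -> list[StratumCounts]:
    """Aggregate screened cases and participating beds into (N_i, n_i, X_i).

    Cases at non-participating hospitals are rejected (they cannot occur in
    a database extract); a stratum with observed cases but zero
    participating beds is an inconsistency.
    """
    hosp = hospitals.set_index("hospital_id")
    unknown = set(cases["hospital_id"]) - set(hosp.index) if len(cases) else set()
    if unknown:
        raise ValidationError(f"cases reference unknown hospitals: {sorted(unknown)[:5]}")

    db_beds = {s.index: 0 for s in strata}
    for _, h in hospitals.iterrows():
        if h["participates"]:
            db_beds[assign_stratum(int(h["beds"]), strata).index] += int(h["beds"])

    x = {s.index: 0 for s in strata}
    for hid, cnt in cases["hospital_id"].value_counts().items():
        if not bool(hosp.at[hid, "participates"]):
            raise ValidationError(f"case at non-participating hospital {hid}")
        x[assign_stratum(int(hosp.at[hid, "beds"]), strata).index] += int(cnt)

    out = []
    for s in strata:
        n_nat = int(national_beds.get(s.index, 0))
        if db_beds[s.index] == 0:
            if x[s.index] > 0:
                raise ValidationError(
                    f"stratum {s.index}: {x[s.index]} cases but no participating beds"
                )
            if n_nat > 0:
                raise ValidationError(
                    f"stratum {s.index}: national beds present but none participating; "
                    "cannot scale up"
                )
            continue  # stratum empty both nationally and in-database
        out.append(
            StratumCounts(stratum=s, national_beds=n_nat, db_beds=db_beds[s.index], cases=x[s.index])
        )
    return out


def estimate_stratum(
    counts: StratumCounts, z: float = DEFAULT_Z, annualization: float = DEFAULT_ANNUALIZATION
) -> StratumEstimate:
    """Annualized national case estimate for one stratum with a Wald CI."""
    if annualization <= 0:
        raise ValidationError("annualization must be > 0")
    n, big_n, x = counts.db_beds, counts.national_beds, counts.cases
    p = annualization * x / n
    if p > 1:
        raise EstimationError(
            f"stratum {counts.stratum.index}: annualized per-bed proportion {p:.3g} > 1"
        )
    half = z * math.sqrt(p * (1 - p) / n)
    low = min(max(big_n * (p - half), 0.0), big_n)
    high = min(max(big_n * (p + half), 0.0), big_n)
    return StratumEstimate(
        stratum=counts.stratum, cases_per_bed=p, estimate=p * big_n, ci_low=low, ci_high=high
    )


def aggregate_national(
    estimates: Iterable[StratumEstimate],
    births: int = DEFAULT_BIRTHS,
    strata: Sequence[StratumDefinition] = DEFAULT_STRATA,
) -> NationalEstimate:
    """Combine stratum estimates into the national annual total and CI."""
    ests = {e.stratum.index: e for e in estimates}
    missing = [s.index for s in strata if s.index not in ests]
    if missing:
        raise ValidationError(f"missing stratum estimates: {missing}")
    ordered = [ests[s.index] for s in strata]
    total_unrounded = sum(e.estimate for e in ordered)
    total = math.trunc(total_unrounded)
    ci_low = sum(round_half_up(e.ci_low) for e in ordered)
    ci_high = sum(round_half_up(e.ci_high) for e in ordered)
    inc = incidence_per_100k(total, births)
    return NationalEstimate(
        total=total,
        ci_low=ci_low,
        ci_high=ci_high,
        incidence_per_100k=inc,
        incidence_ci=(
            incidence_per_100k(ci_low, births),
            incidence_per_100k(ci_high, births),
        ),
        births_denominator=births,
        total_unrounded=total_unrounded,
    )


def incidence_per_100k(total_cases: float, births: int = DEFAULT_BIRTHS) -> float:
    """Annual cases per 100,000 infants of the birth cohort (unrounded)."""
    if births <= 0:
        raise ValidationError("births must be > 0")
    return total_cases / births * 100_000


def exact_binomial_ci(x: int, n: int, level: float = 0.95) -> ExactBinomialCI:
    """Clopper-Pearson exact confidence interval for x successes in n trials.

    Inverts the binomial tail probabilities (via the beta quantile), so the
    interval's coverage is at least ``level`` for every true proportion;
    low is exactly 0 when x = 0 and high exactly 1 when x = n.
    """
    if n < 1 or not 0 <= x <= n:
        raise ValidationError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    low, high = proportion_confint(x, n, alpha=1 - level, method="beta")
    low = 0.0 if x == 0 else float(low)
    high = 1.0 if x == n else float(high)
    return ExactBinomialCI(successes=x, trials=n, level=level, low=low, high=high)


def read_strata_counts(
    path, strata: Sequence[StratumDefinition] = DEFAULT_STRATA
) -> list[StratumCounts]:
    """Read a strata-counts CSV (stratum, national_beds, db_beds, cases_half_year)."""
    df = pd.read_csv(path)
    by_index = {s.index: s for s in strata}
    return [
        StratumCounts(
            stratum=by_index[int(r["stratum"])],
            national_beds=int(r["national_beds"]),
            db_beds=int(r["db_beds"]),
            cases=int(r["cases_half_year"]),
        )
        for _, r in df.iterrows()
    ]


def estimates_frame(
    estimates: Sequence[StratumEstimate], national: Optional[NationalEstimate] = None
) -> pd.DataFrame:
    """Tabulate stratum estimates (unrounded and report-rounded columns)."""
    rows = [
        {
            "stratum": e.stratum.index,
            "label": e.stratum.label,
            "cases_per_bed": e.cases_per_bed,
            "estimate": e.estimate,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "report_estimate": round_half_up(e.estimate),
            "report_ci_low": round_half_up(e.ci_low),
            "report_ci_high": round_half_up(e.ci_high),
        }
        for e in estimates
    ]
    if national is not None:
        rows.append(
            {
                "stratum": 0,
                "label": "Total",
                "cases_per_bed": float("nan"),
                "estimate": national.total_unrounded,
                "ci_low": national.ci_low,
                "ci_high": national.ci_high,
                "report_estimate": national.total,
                "report_ci_low": national.ci_low,
                "report_ci_high": national.ci_high,
            }
        )
    return pd.DataFrame(rows)
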