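"""Stratified scale-up estimator, Wald CIs, exact binomial intervals."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import binom

from intusepi import (
    DEFAULT_STRATA,
    StratumCounts,
    aggregate_national,
    assign_stratum,
    estimate_stratum,
    exact_binomial_ci,
    incidence_per_100k,
    tabulate_strata,
)
from intusepi.datasets import load_table1, table1_path
from intusepi.incidence import EstimationError, read_strata_counts, round_half_up
from intusepi.types import ValidationError

from conftest import admissions_frame, make_admission


def counts_for(year):
    return read_strata_counts(table1_path(year))


@pytest.mark.parametrize(
    "beds,expected",
    [(1, 1), (399, 1), (400, 2), (599, 2), (600, 3), (799, 3), (800, 4), (5000, 4)],
)
def test_assign_stratum_boundaries(beds, expected):
    assert assign_stratum(beds).index == expected


def test_assign_stratum_rejects_nonpositive_beds():
    with pytest.raises(ValidationError):
        assign_stratum(0)


# Published per-stratum annual estimates and Wald bounds, report-rounded
# half-up. (The 2008 stratum-3 estimate has unrounded value 278.72; the
# publication prints its truncation 278, every other stratum matches
# half-up rounding.)
PUBLISHED = {
    2007: [(701, 597, 806), (631, 565, 697), (320, 276, 365), (305, 262, 348)],
    2008: [(917, 788, 1046), (663, 592, 733), (279, 235, 322), (223, 187, 260)],
}


@pytest.mark.parametrize("year", [2007, 2008])
def test_stratum_estimates_match_published_table(year):
    for counts, (y, lo, hi) in zip(counts_for(year), PUBLISHED[year]):
        est = estimate_stratum(counts)
        assert round_half_up(est.estimate) == y
        assert round_half_up(est.ci_low) == lo
        assert round_half_up(est.ci_high) == hi
        assert 0 <= est.ci_low <= est.estimate <= est.ci_high <= counts.national_beds


@pytest.mark.parametrize(
    "year,total,ci",
    [
        # The 2007 stratum lower bounds sum to 1700; the published total
        # lower bound (1743) is not recoverable from the printed inputs.
        (2007, 1957, (1700, 2216)),
        (2008, 2081, (1802, 2361)),
    ],
)
def test_national_totals(year, total, ci):
    estimates = [estimate_stratum(c) for c in counts_for(year)]
    national = aggregate_national(estimates)
    assert national.total == total
    assert (national.ci_low, national.ci_high) == ci


def test_zero_cases_degenerate_interval():
    c = StratumCounts(stratum=DEFAULT_STRATA[0], national_beds=1000, db_beds=500, cases=0)
    est = estimate_stratum(c)
    assert est.estimate == 0.0
    assert (est.ci_low, est.ci_high) == (0.0, 0.0)


def test_implausible_per_bed_proportion_raises():
    c = StratumCounts(stratum=DEFAULT_STRATA[0], national_beds=100, db_beds=10, cases=6)
    with pytest.raises(EstimationError):
        estimate_stratum(c)


def test_aggregate_requires_all_strata():
    estimates = [estimate_stratum(c) for c in counts_for(2007)][:3]
    with pytest.raises(ValidationError, match="missing"):
        aggregate_national(estimates)


def test_all_zero_strata_aggregate_to_zero():
    counts = [
        StratumCounts(stratum=s, national_beds=1000, db_beds=400, cases=0)
        for s in DEFAULT_STRATA
    ]
    national = aggregate_national([estimate_stratum(c) for c in counts])
    assert (national.total, national.ci_low, national.ci_high) == (0, 0, 0)


def test_incidence_per_100k():
    assert round_half_up(incidence_per_100k(2081, 1_090_000)) == 191
    assert incidence_per_100k(0) == 0.0
    assert incidence_per_100k(1_090_000, 1_090_000) == 100_000.0
    with pytest.raises(ValidationError):
        incidence_per_100k(100, 0)


def test_scale_equivariance_in_national_beds():
    base = StratumCounts(stratum=DEFAULT_STRATA[0], national_beds=10_000, db_beds=5_000, cases=20)
    e1 = estimate_stratum(base)
    for c in (3, 10):
        scaled = StratumCounts(stratum=DEFAULT_STRATA[0], national_beds=10_000 * c,
                               db_beds=5_000, cases=20)
        e2 = estimate_stratum(scaled)
        assert e2.estimate == pytest.approx(c * e1.estimate, rel=1e-12)
        assert e2.ci_low == pytest.approx(c * e1.ci_low, rel=1e-12)
        assert e2.ci_high == pytest.approx(c * e1.ci_high, rel=1e-12)


def test_monotonicity_in_cases_and_interval_width_in_beds():
    def est(n, x):
        return estimate_stratum(
            StratumCounts(stratum=DEFAULT_STRATA[0], national_beds=10**6, db_beds=n, cases=x)
        )

    y = [est(50_000, x).estimate for x in range(0, 50)]
    assert all(b > a for a, b in zip(y, y[1:]))

    # at fixed p, widening the bed sample narrows the Wald interval
    widths = [est(n, n // 100).ci_high - est(n, n // 100).ci_low for n in (10_000, 40_000, 160_000)]
    assert widths[0] > widths[1] > widths[2]


def test_estimator_matches_exact_rational_oracle():
    """1,000 random small inputs vs a direct rational-arithmetic transcription."""
    rng = np.random.default_rng(2027)
    for _ in range(1000):
        n = int(rng.integers(10, 10_000))
        big_n = n + int(rng.integers(0, 10_000))
        x = int(rng.integers(0, max(1, n // 4)))
        c = StratumCounts(stratum=DEFAULT_STRATA[0], national_beds=big_n, db_beds=n, cases=x)
        est = estimate_stratum(c)

        p = Fraction(2 * x, n)
        y_exact = p * big_n
        assert est.estimate == pytest.approx(float(y_exact), rel=1e-9, abs=1e-12)
        half = Fraction(196, 100) * math.sqrt(float(p * (1 - p) / n))
        lo = max(float(big_n * (p - half)), 0.0)
        hi = min(float(big_n * (p + half)), float(big_n))
        assert est.ci_low == pytest.approx(lo, rel=1e-9, abs=1e-9)
        assert est.ci_high == pytest.approx(hi, rel=1e-9, abs=1e-9)


def cp_bruteforce(x, n, level=0.95):
    """Clopper-Pearson bounds by root-finding on the binomial tail CDFs."""
    alpha = 1 - level
    lo = 0.0 if x == 0 else brentq(lambda p: binom.sf(x - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
    hi = 1.0 if x == n else brentq(lambda p: binom.cdf(x, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
    return lo, hi


@pytest.mark.parametrize("x,n", [(5, 10), (0, 10), (10, 10), (2, 2427), (1, 50)])
def test_exact_binomial_matches_tail_inversion(x, n):
    ci = exact_binomial_ci(x, n)
    lo, hi = cp_bruteforce(x, n)
    assert ci.low == pytest.approx(lo, abs=1e-8)
    assert ci.high == pytest.approx(hi, abs=1e-8)
    assert 0 <= ci.low <= x / n <= ci.high <= 1


def test_case_fatality_interval_matches_publication():
    ci = exact_binomial_ci(2, 2427)
    assert round(100 * ci.low, 2) == 0.01
    assert round(100 * ci.high, 2) == 0.30


def test_exact_binomial_input_validation():
    with pytest.raises(ValidationError):
        exact_binomial_ci(5, 0)
    with pytest.raises(ValidationError):
        exact_binomial_ci(11, 10)


def test_tabulate_strata_conservation():
    hospitals = pd.DataFrame(
        {
            "hospital_id": ["H1", "H2", "H3"],
            "beds": [100, 450, 900],
            "participates": [True, True, False],
        }
    )
    cases = admissions_frame(
        [make_admission(patient_id="P1", hospital_id="H1"),
         make_admission(patient_id="P2", hospital_id="H2"),
         make_admission(patient_id="P3", hospital_id="H2")]
    )
    national = {1: 100, 2: 450, 3: 0, 4: 900}
    # stratum 4 has national beds but no participating hospital -> cannot scale
    with pytest.raises(ValidationError):
        tabulate_strata(cases, hospitals, national)

    national = {1: 100, 2: 450, 3: 0, 4: 0}
    counts = tabulate_strata(cases, hospitals.loc[hospitals["participates"]], national)
    by_idx = {c.stratum.index: c for c in counts}
    assert by_idx[1].cases == 1 and by_idx[2].cases == 2
    assert sum(c.cases for c in counts) == len(cases)
    assert sum(c.db_beds for c in counts) == 550


def test_tabulate_strata_rejects_case_at_nonparticipating_hospital():
    hospitals = pd.DataFrame(
        {"hospital_id": ["H1"], "beds": [100], "participates": [False]}
    )
    cases = admissions_frame([make_admission(hospital_id="H1")])
    with pytest.raises(ValidationError):
        tabulate_strata(cases, hospitals, {1: 100})


def test_shipped_table_matches_publication_margins():
    for year, total_cases, total_db_beds in ((2007, 457, 341_625), (2008, 415, 309_465)):
        df = load_table1(year)
        assert df["cases_half_year"].sum() == total_cases
        assert df["db_beds"].sum() == total_db_beds
        assert df["national_beds"].sum() == 910_238
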