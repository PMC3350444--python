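"""Case ascertainment: diagnosis-code screening, diagnostic-certainty
filtering, and same-hospital readmission tagging.

Screening retains admissions that (1) carry a diagnosis code matching the
intussusception prefix (K561; code dialects with or without the dot are
normalized), (2) are at most 18 completed years old at admission, and
(3) have level-1 diagnostic certainty, i.e. surgical, radiological or
autopsy confirmation. Everything else coded as intussusception is excluded.
Readmissions to the same hospital are tagged but kept as independent rows —
they are never merged or dropped downstream.
"""

from __future__ import annotations

import logging

import pandas as pd

from .types import ScreenCriteria, ValidationError

logger = logging.getLogger(__name__)


def normalize_icd10(code: str) -> str:
    """Strip dots and whitespace and upper-case an ICD-10 code."""
    return code.replace(".", "").strip().upper()


def _matches_prefix(codes_field, prefix: str) -> bool:
    if codes_field is None or (isinstance(codes_field, float) and pd.isna(codes_field)):
        return False
    if isinstance(codes_field, str):
        codes = codes_field.split(";")
    else:
        codes = list(codes_field)
    return any(normalize_icd10(c).startswith(prefix) for c in codes)


def screen_cases(
    records: pd.DataFrame, criteria: ScreenCriteria = ScreenCriteria()
) -> pd.DataFrame:
    """Select analyzable intussusception cases from raw admission records.

    Returns the retained rows in their original order. Emits a screening
    log with counts in/out per criterion. Records with a malformed
    diagnosis-code field raise :class:`ValidationError` naming the record.
    """
    if len(records) == 0:
        return records.copy()

    prefix = normalize_icd10(criteria.icd10_prefix)
    bad = records["icd10_codes"].isna()
    if bad.any():
        rid = records.loc[bad].iloc[0]
        raise ValidationError(f"record {rid['patient_id']}: missing icd10_codes field")

    has_code = records["icd10_codes"].map(lambda c: _matches_prefix(c, prefix))
    age_ok = (records["age_months"] // 12) <= criteria.max_age_years
    evidence_ok = records["brighton_evidence"].isin(criteria.required_brighton)
    keep = has_code & age_ok & evidence_ok

    logger.info(
        "screening: %d records in; %d match %s; %d within age cap; "
        "%d with required evidence; %d retained",
        len(records), int(has_code.sum()), criteria.icd10_prefix,
        int((has_code & age_ok).sum()), int((has_code & evidence_ok).sum()),
        int(keep.sum()),
    )
    return records.loc[keep].copy()


def excluded_cases(
    records: pd.DataFrame, criteria: ScreenCriteria = ScreenCriteria()
) -> pd.DataFrame:
    """The complement of :func:`screen_cases` (for the exclusions CSV)."""
    kept_index = screen_cases(records, criteria).index
    return records.loc[~records.index.isin(kept_index)].copy()


def tag_readmissions(cases: pd.DataFrame, window_days: int = 7) -> pd.DataFrame:
    """Tag same-patient, same-hospital readmissions within a window.

    A row is a readmission iff the same patient has an earlier case
    discharge at the same hospital with ``0 <= admit - prior_discharge <=
    window_days`` (whole days, discharge-to-admission). Adds boolean
    ``is_readmission`` and nullable integer ``gap_days`` columns; no rows
    are removed or merged. Rows without patient linkage are never tagged.
    """
    out = cases.copy()
    out["is_readmission"] = False
    out["gap_days"] = pd.array([None] * len(out), dtype="Int64")
    if len(out) == 0:
        return out

    for (_, _), grp in out.groupby(["patient_id", "hospital_id"], sort=False):
        if len(grp) < 2:
            continue
        ordered = grp.sort_values(["admit_date", "discharge_date"], kind="stable")
        prior_discharge = None
        for idx, row in ordered.iterrows():
            if prior_discharge is not None:
                gap = (row["admit_date"] - prior_discharge).days
                if 0 <= gap <= window_days:
                    out.at[idx, "is_readmission"] = True
                    out.at[idx, "gap_days"] = gap
            if prior_discharge is None or row["discharge_date"] > prior_discharge:
                prior_discharge = row["discharge_date"]
    return out
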