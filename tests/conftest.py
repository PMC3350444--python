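from datetime import date

import pandas as pd
import pytest

from intusepi import GeneratorConfig


def make_admission(
    patient_id="P1",
    hospital_id="H1",
    age_months=17,
    sex="male",
    admit_date=date(2007, 8, 1),
    discharge_date=date(2007, 8, 4),
    icd10_codes="K56.1",
    brighton_evidence="radiological",
    treatment="enema_success",
    secondary_cause=None,
    complication="none",
    died=False,
):
    return {
        "patient_id": patient_id,
        "hospital_id": hospital_id,
        "age_months": age_months,
        "sex": sex,
        "admit_date": admit_date,
        "discharge_date": discharge_date,
        "icd10_codes": icd10_codes,
        "brighton_evidence": brighton_evidence,
        "treatment": treatment,
        "secondary_cause": secondary_cause,
        "complication": complication,
        "died": died,
    }


def admissions_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture
def small_config():
    """A fast generator configuration: case records only, no background."""
    return GeneratorConfig(seed=7, n_hospitals=120, background_rate_per_bed=0.0)
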