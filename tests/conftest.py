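import numpy as np
import pandas as pd
import pytest

import crcdelay as cd


@pytest.fixture(scope="session")
def study():
    return cd.StudyConfig()


@pytest.fixture(scope="session")
def default_cohort(study):
    """A moderate default-configuration synthetic cohort, fully linked."""
    sim = cd.SimulationConfig(n_patients=10_000, seed=11)
    cohort = cd.generate_cohort(sim)
    patients = cd.assign_period(cohort.patients, study)
    linked = cd.link_lookback(patients, cohort.events, study)
    patients, _ = cd.exclude_no_milestones(patients, linked)
    return {"sim": sim, "patients": patients, "events": cohort.events,
            "truth": cohort.truth, "linked": linked}


def make_events(rows):
    """Build an events frame from (patient_id, date, category[, setting]) tuples."""
    records = []
    for row in rows:
        pid, date, category = row[:3]
        setting = row[3] if len(row) > 3 else "ambulatory"
        records.append({"patient_id": pid, "event_date": pd.Timestamp(date),
                        "category": category, "raw_code": "",
                        "blood_subtype": "none", "setting": setting,
                        "fit_result": "unknown"})
    return pd.DataFrame(records)


def make_patients(rows):
    """Build a patients frame from (patient_id, diagnosis_date[, age, sex]) tuples."""
    records = []
    for row in rows:
        pid, dx = row[:2]
        age = row[2] if len(row) > 2 else 65
        sex = row[3] if len(row) > 3 else "male"
        records.append({"patient_id": pid, "sex": sex, "age_at_diagnosis": age,
                        "diagnosis_date": pd.Timestamp(dx), "cancer_site": "colon"})
    return pd.DataFrame(records)
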