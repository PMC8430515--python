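"""Synthetic administrative-data generator.

Emulates a provincial registry / hospital-abstract / ambulatory-care linkage
for colorectal cancer: a diagnosed cohort with demographics, per-patient
milestone event histories in the year before diagnosis, and a monthly
colonoscopy procedure stream with linked CRC diagnoses.

Each patient is assigned a latent diagnostic pathway:

* ``screening``  — positive FIT, then colonoscopy on the diagnosis date;
* ``blood_test`` — primary-care blood work (iron/ferritin/MCV/hemoglobin),
  then colonoscopy;
* ``symptom``    — a symptom or bowel-obstruction diagnosis in urgent care,
  then colonoscopy and/or surgery;
* ``unclassified`` — a procedure-only history with no recorded initiator.

Waiting times between milestones are drawn from log-normal distributions
parameterized by (median, IQR); defaults reproduce the pre-pandemic interval
table the downstream stages are benchmarked against. The hospital-diagnosis
outcome (an inpatient diagnostic procedure on the diagnosis date, the proxy
for severe presentation) follows a multiplicative-risk (log-link) model so
the configured relative risks are exactly the estimands of the modified
Poisson stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .registry import CodeTable, EVENT_COLUMNS

_Z75 = norm.ppf(0.75)


def lognormal_sigma(median_days: float, iqr_days: float) -> float:
    """Log-scale sigma such that a log-normal with the given median has the
    given interquartile range: Q3 - Q1 = 2 * median * sinh(sigma * z75)."""
    if median_days <= 0:
        raise ValueError("median_days must be positive")
    if iqr_days < 0:
        raise ValueError("iqr_days must be nonnegative")
    return math.asinh(iqr_days / (2.0 * median_days)) / _Z75


def sample_interval(median_days: float, iqr_days: float,
                    rng: np.random.Generator, size: int | None = None):
    """Draw integer waiting times (days) from a log-normal with the given
    median and IQR; ``iqr_days == 0`` degenerates to the constant median."""
    sigma = lognormal_sigma(median_days, iqr_days)
    n = 1 if size is None else size
    if sigma == 0.0:
        draws = np.full(n, float(median_days))
    else:
        draws = median_days * np.exp(sigma * rng.standard_normal(n))
    out = np.rint(draws).astype(int)
    return int(out[0]) if size is None else out


class SimulatedCohort(NamedTuple):
    patients: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame  # latent pathway and hospital-diagnosis outcome


# Table-1-style age bands: (lo, hi, probability)
_AGE_BANDS = (
    (18, 39, 0.0347),
    (40, 49, 0.0717),
    (50, 59, 0.1858),
    (60, 69, 0.2708),
    (70, 79, 0.2452),
    (80, 95, 0.1918),
)

_SITES = ("colon", "rectosigmoid_junction", "rectum")
_SITE_P = (0.672, 0.040, 0.288)

_SYMPTOM_CHOICES = ("rectal_bleeding", "abdominal_pain", "bowel_habit_change", "weight_loss")
_SYMPTOM_P = (0.45, 0.30, 0.15, 0.10)


def _default_interval_params() -> dict[str, tuple[float, float]]:
    # (median days, IQR days), pre-pandemic interval table
    return {
        "fit_to_colonoscopy": (72.0, 86.0),
        "blood_to_colonoscopy": (55.0, 95.0),
        "symptom_to_colonoscopy": (3.0, 31.0),
        "ct_to_diagnosis": (7.0, 44.0),
        "colonoscopy_to_diagnosis": (0.0, 0.0),
        "surgery_to_diagnosis": (0.0, 0.0),
    }


def _default_capacity_schedule() -> dict[str, float]:
    # Monthly FIT/colonoscopy capacity multipliers during the first pandemic
    # wave: mid-March pause, full April suspension, partial mid-May resumption,
    # ~80% of pre-pandemic capacity thereafter.
    sched = {"2020-03": 0.5, "2020-04": 0.0, "2020-05": 0.5}
    for m in range(6, 13):
        sched[f"2020-{m:02d}"] = 0.8
    return sched


@dataclass
class SimulationConfig:
    """Parameters of the synthetic registry; defaults are the study
    conditions the analysis stages are validated against."""

    n_patients: int = 10_000
    seed: int = 0

    # periods
    pre_start: date = date(2016, 1, 1)
    pre_end: date = date(2020, 2, 29)
    intra_start: date = date(2020, 3, 1)
    intra_end: date = date(2020, 7, 1)
    intra_fraction: float = 0.0403  # intra share of the diagnosed cohort

    # pathway structure
    pathway_mix: tuple[float, float, float] = (0.312, 0.474, 0.205)  # pre
    pathway_mix_intra: tuple[float, float, float] = (0.159, 0.461, 0.382)
    unclassified_fraction: float = 0.248
    obstruction_given_symptom: float = 0.6
    second_blood_test_fraction: float = 0.16
    ct_fraction: float = 0.28
    surgery_fraction: float = 0.5
    symptom_colonoscopy_fraction: float = 0.65
    unclassified_colonoscopy_fraction: float = 0.7

    interval_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_interval_params)
    lookback_days: int = 365

    # hospital-diagnosis (severity proxy) risk model, log link
    baseline_hospital_risk: float = 0.18
    severity_effects: dict[str, float] = field(default_factory=lambda: {
        "intra": math.log(1.24),
        "age_per_year": math.log(1.01),
        "female": math.log(1.05),
        "fit": math.log(0.47),
        "obstruction": math.log(2.88),
    })
    age_reference: float = 65.0

    # procedure stream
    monthly_colonoscopy_volume: int = 8000
    baseline_yield: float = 0.0166
    colonoscopy_fraction: float = 0.856
    stream_start: str = "2019-01"
    stream_end: str = "2020-12"
    intra_capacity_schedule: dict[str, float] = field(
        default_factory=_default_capacity_schedule)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        for name in ("intra_fraction", "unclassified_fraction", "baseline_yield",
                     "baseline_hospital_risk"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.colonoscopy_fraction <= 1.0:
            raise ValueError("colonoscopy_fraction must be in (0, 1]")
        total = sum(self.pathway_mix)
        if total <= 0:
            raise ValueError("pathway_mix must have positive mass")
        self.pathway_mix = tuple(p / total for p in self.pathway_mix)
        total = sum(self.pathway_mix_intra)
        self.pathway_mix_intra = tuple(p / total for p in self.pathway_mix_intra)


def _random_dates(rng: np.random.Generator, start: date, end: date, n: int) -> np.ndarray:
    lo = np.datetime64(start, "D")
    hi = np.datetime64(end, "D")
    span = int((hi - lo) / np.timedelta64(1, "D")) + 1
    return lo + rng.integers(0, span, n).astype("timedelta64[D]")


def _draw_ages(rng: np.random.Generator, n: int) -> np.ndarray:
    probs = np.array([b[2] for b in _AGE_BANDS])
    probs = probs / probs.sum()
    band = rng.choice(len(_AGE_BANDS), size=n, p=probs)
    lo = np.array([b[0] for b in _AGE_BANDS])[band]
    hi = np.array([b[1] for b in _AGE_BANDS])[band]
    return lo + (rng.random(n) * (hi - lo + 1)).astype(int)


def generate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a diagnosed cohort and its milestone event table.

    Fully reproducible under ``config.seed``. Raises if the log-link risk
    model would exceed probability 1 for more than 1% of patients (advice:
    lower ``baseline_hospital_risk``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cols = {c: [] for c in EVENT_COLUMNS}
    if n == 0:
        patients = pd.DataFrame(columns=["patient_id", "sex", "age_at_diagnosis",
                                         "diagnosis_date", "cancer_site"])
        events = pd.DataFrame(cols)
        truth = pd.DataFrame(columns=["patient_id", "pathway", "hospital_diagnosis"])
        return SimulatedCohort(patients, events, truth)

    pid = np.array([f"P{i:06d}" for i in range(n)])
    intra = rng.random(n) < config.intra_fraction
    dx = np.empty(n, dtype="datetime64[D]")
    dx[~intra] = _random_dates(rng, config.pre_start, config.pre_end, int((~intra).sum()))
    dx[intra] = _random_dates(rng, config.intra_start, config.intra_end, int(intra.sum()))
    age = _draw_ages(rng, n)
    female = rng.random(n) < 0.4268
    site = rng.choice(_SITES, size=n, p=_SITE_P)

    # latent pathway
    classified = rng.random(n) >= config.unclassified_fraction
    groups = np.array(["screening", "blood_test", "symptom"])
    pathway = np.full(n, "unclassified", dtype=object)
    pre_cls = classified & ~intra
    intra_cls = classified & intra
    pathway[pre_cls] = rng.choice(groups, size=int(pre_cls.sum()), p=config.pathway_mix)
    pathway[intra_cls] = rng.choice(groups, size=int(intra_cls.sum()),
                                    p=config.pathway_mix_intra)

    is_screen = pathway == "screening"
    is_blood = pathway == "blood_test"
    is_symp = pathway == "symptom"
    is_uncls = pathway == "unclassified"
    obstruction = is_symp & (rng.random(n) < config.obstruction_given_symptom)

    # hospital-diagnosis outcome, multiplicative risk
    eff = config.severity_effects
    logp = (math.log(config.baseline_hospital_risk)
            + eff["intra"] * intra
            + eff["age_per_year"] * (age - config.age_reference)
            + eff["female"] * female
            + eff["fit"] * is_screen
            + eff["obstruction"] * obstruction)
    p = np.exp(logp)
    if (p > 1).mean() > 0.01:
        raise ValueError("hospital-diagnosis risk exceeds 1 for >1% of patients; "
                         "lower baseline_hospital_risk")
    hosp = rng.random(n) < np.minimum(p, 1.0)

    table = CodeTable.default()
    code_pool = {cat: np.array(table.codes_for(cat)) for cat in
                 ("colonoscopy", "surgery", "ct", "rectal_bleeding", "abdominal_pain",
                  "weight_loss", "bowel_habit_change", "bowel_obstruction")}
    # drop the transcription variant so emitted surgery codes are canonical
    code_pool["surgery"] = np.array([c for c in code_pool["surgery"] if c != "INM87"])

    max_back = config.lookback_days - 1

    def add(mask_or_idx, offsets, category, *, setting, subtype="none",
            fit_result="unknown", coded=True):
        idx = np.flatnonzero(mask_or_idx) if mask_or_idx.dtype == bool else mask_or_idx
        if idx.size == 0:
            return
        offsets = np.asarray(offsets)
        cols["patient_id"].append(pid[idx])
        cols["event_date"].append(dx[idx] - offsets.astype("timedelta64[D]"))
        cols["category"].append(np.full(idx.size, category, dtype=object))
        if coded and category in code_pool:
            cols["raw_code"].append(rng.choice(code_pool[category], size=idx.size))
        else:
            cols["raw_code"].append(np.full(idx.size, "", dtype=object))
        cols["blood_subtype"].append(
            subtype if isinstance(subtype, np.ndarray)
            else np.full(idx.size, subtype, dtype=object))
        cols["setting"].append(
            setting if isinstance(setting, np.ndarray)
            else np.full(idx.size, setting, dtype=object))
        cols["fit_result"].append(np.full(idx.size, fit_result, dtype=object))

    ip = config.interval_params

    # --- screening: positive FIT, then colonoscopy on the diagnosis date
    g_fit = np.clip(sample_interval(*ip["fit_to_colonoscopy"], rng, int(is_screen.sum())),
                    1, max_back)
    add(is_screen, g_fit, "fit", setting="community", fit_result="positive", coded=False)

    # --- blood-test pathway: community lab work, then colonoscopy at diagnosis
    nb = int(is_blood.sum())
    g_blood = np.clip(sample_interval(*ip["blood_to_colonoscopy"], rng, nb), 1, max_back)
    subtypes = rng.choice(np.array(["iron", "ferritin", "mcv", "hemoglobin"]), size=nb)
    add(is_blood, g_blood, "blood_test", setting="community", subtype=subtypes, coded=False)
    # a fraction get a repeat test midway between the first and diagnosis
    second_gap = np.clip(g_blood // 2, 1, max_back)
    sel = rng.random(nb) < config.second_blood_test_fraction
    add(np.flatnonzero(is_blood)[sel], second_gap[sel], "blood_test",
        setting="community",
        subtype=rng.choice(np.array(["iron", "ferritin", "mcv", "hemoglobin"]),
                           size=int(sel.sum())),
        coded=False)

    # --- symptom pathway: urgent-care symptom/obstruction diagnosis
    ns = int(is_symp.sum())
    g_sym = np.clip(sample_interval(*ip["symptom_to_colonoscopy"], rng, ns), 0, max_back)
    symp_cat = np.where(
        obstruction[is_symp], "bowel_obstruction",
        rng.choice(np.array(_SYMPTOM_CHOICES), size=ns, p=np.array(_SYMPTOM_P)))
    symp_setting = np.where(rng.random(ns) < 0.5, "inpatient", "ambulatory")
    symp_idx = np.flatnonzero(is_symp)
    for cat in np.unique(symp_cat):
        m = symp_cat == cat
        add(symp_idx[m], g_sym[m], str(cat), setting=symp_setting[m])

    # --- diagnosis-date procedures (every patient gets at least one)
    has_colo = np.zeros(n, dtype=bool)
    has_colo[is_screen | is_blood] = True
    has_colo[is_symp] = rng.random(n)[is_symp] < config.symptom_colonoscopy_fraction
    has_colo[is_uncls] = rng.random(n)[is_uncls] < config.unclassified_colonoscopy_fraction
    has_surg = rng.random(n) < config.surgery_fraction
    has_colo[~has_colo & ~has_surg] = True  # guarantee a diagnosis-date procedure

    # hospital-diagnosed patients get an inpatient procedure on the dx date
    colo_setting = np.where(hosp & has_colo, "inpatient", "ambulatory")
    surg_setting = np.where(hosp & ~has_colo, "inpatient", "ambulatory")
    zeros = np.zeros(n, dtype=int)
    add(has_colo, zeros[has_colo], "colonoscopy", setting=colo_setting[has_colo])
    add(has_surg, zeros[has_surg], "surgery", setting=surg_setting[has_surg])

    # --- CT scans a few days before diagnosis, ambulatory
    has_ct = rng.random(n) < config.ct_fraction
    g_ct = np.clip(sample_interval(*ip["ct_to_diagnosis"], rng, int(has_ct.sum())),
                   0, max_back)
    add(has_ct, g_ct, "ct", setting="ambulatory")

    events = pd.DataFrame({c: np.concatenate(cols[c]) if cols[c] else np.array([])
                           for c in EVENT_COLUMNS})
    events["event_date"] = pd.to_datetime(events["event_date"])
    events = events.sort_values(["patient_id", "event_date", "category"],
                                kind="mergesort").reset_index(drop=True)

    patients = pd.DataFrame({
        "patient_id": pid,
        "sex": np.where(female, "female", "male"),
        "age_at_diagnosis": age,
        "diagnosis_date": pd.to_datetime(dx),
        "cancer_site": site,
    })
    truth = pd.DataFrame({"patient_id": pid, "pathway": pathway,
                          "hospital_diagnosis": hosp,
                          "period": np.where(intra, "intra", "pre")})
    return SimulatedCohort(patients, events, truth)


def generate_procedure_stream(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly colonoscopy records with linked CRC diagnoses.

    Per calendar month, ``monthly_colonoscopy_volume`` scaled by that month's
    capacity multiplier procedures are dated uniformly within the month; a
    Bernoulli(``baseline_yield``) subset is followed by a CRC diagnosis 0-30
    days after the procedure.
    """
    if config.monthly_colonoscopy_volume <= 0:
        raise ValueError("monthly_colonoscopy_volume must be positive")
    rng = np.random.default_rng(config.seed + 1)
    months = pd.period_range(config.stream_start, config.stream_end, freq="M")
    proc_frames = []
    counter = 0
    for month in months:
        mult = config.intra_capacity_schedule.get(str(month), 1.0)
        volume = int(round(config.monthly_colonoscopy_volume * mult))
        if volume == 0:
            continue
        start = month.to_timestamp().to_datetime64().astype("datetime64[D]")
        days = month.days_in_month
        dates = start + rng.integers(0, days, volume).astype("timedelta64[D]")
        ids = np.array([f"S{counter + i:07d}" for i in range(volume)])
        counter += volume
        proc_frames.append(pd.DataFrame({"patient_id": ids,
                                         "procedure_date": pd.to_datetime(dates)}))
    procedures = (pd.concat(proc_frames, ignore_index=True) if proc_frames
                  else pd.DataFrame(columns=["patient_id", "procedure_date"]))
    diagnosed = rng.random(len(procedures)) < config.baseline_yield
    lags = rng.integers(0, 31, int(diagnosed.sum())).astype("timedelta64[D]")
    diagnoses = pd.DataFrame({
        "patient_id": procedures.loc[diagnosed, "patient_id"].to_numpy(),
        "diagnosis_date": pd.to_datetime(
            procedures.loc[diagnosed, "procedure_date"].to_numpy().astype("datetime64[D]")
            + lags),
    })
    return procedures, diagnoses
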