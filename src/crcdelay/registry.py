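"""Domain model for a registry-linked colorectal cancer (CRC) cohort.

A study cohort is held as two plain tables:

``patients``
    One row per diagnosed patient: ``patient_id``, ``sex`` (male/female),
    ``age_at_diagnosis`` (integer years), ``diagnosis_date``,
    ``cancer_site`` (colon / rectosigmoid_junction / rectum), and — once
    :func:`assign_period` has run — ``period`` (pre / intra).

``events``
    One row per dated diagnostic milestone: ``patient_id``, ``event_date``,
    ``category`` (see :data:`CATEGORIES`), ``blood_subtype``, ``raw_code``
    (ICD-10 or CCI, possibly empty), ``setting`` (inpatient / ambulatory /
    community) and ``fit_result`` (positive / negative / unknown).

Milestone categories cover the tests, procedures and symptom diagnoses a
CRC patient may accrue in the year before diagnosis: fecal immunochemical
tests (FIT), primary-care blood work (iron, ferritin, MCV, hemoglobin),
colonoscopy, colorectal surgery, abdominal CT, and coded symptoms (rectal
bleeding, abdominal pain, unexplained weight loss, change in bowel habits,
bowel obstruction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Vocabularies
# ---------------------------------------------------------------------------

CATEGORIES: tuple[str, ...] = (
    "fit",
    "blood_test",
    "colonoscopy",
    "surgery",
    "ct",
    "rectal_bleeding",
    "abdominal_pain",
    "weight_loss",
    "bowel_habit_change",
    "bowel_obstruction",
)

#: Symptom / obstruction diagnoses (pathway initiators via urgent care).
SYMPTOM_CATEGORIES: frozenset[str] = frozenset(
    {"rectal_bleeding", "abdominal_pain", "weight_loss",
     "bowel_habit_change", "bowel_obstruction"}
)

#: Diagnostic tests/procedures (can coincide with a hospital-based diagnosis).
PROCEDURE_CATEGORIES: frozenset[str] = frozenset({"colonoscopy", "surgery", "ct"})

SETTINGS: tuple[str, ...] = ("inpatient", "ambulatory", "community")
BLOOD_SUBTYPES: tuple[str, ...] = ("iron", "ferritin", "mcv", "hemoglobin", "none")
FIT_RESULTS: tuple[str, ...] = ("positive", "negative", "unknown")

PATIENT_COLUMNS = ["patient_id", "sex", "age_at_diagnosis", "diagnosis_date", "cancer_site"]
EVENT_COLUMNS = ["patient_id", "event_date", "category", "raw_code",
                 "blood_subtype", "setting", "fit_result"]

# ---------------------------------------------------------------------------
# ICD-10 / CCI code table
# ---------------------------------------------------------------------------

#: Default milestone code lists (ICD-10 for diagnoses, CCI for procedures).
#: "INM87" is carried verbatim from the surgical code list this table was
#: transcribed from; "1NM87" is also accepted as its obvious intended form.
DEFAULT_CODES: dict[str, tuple[str, str]] = {
    # symptoms (ICD-10)
    "K625": ("rectal_bleeding", "icd10"),
    "K552": ("rectal_bleeding", "icd10"),
    "K922": ("rectal_bleeding", "icd10"),
    "R100": ("abdominal_pain", "icd10"),
    "R101": ("abdominal_pain", "icd10"),
    "R102": ("abdominal_pain", "icd10"),
    "R103": ("abdominal_pain", "icd10"),
    "R104": ("abdominal_pain", "icd10"),
    "R634": ("weight_loss", "icd10"),
    "R194": ("bowel_habit_change", "icd10"),
    "K566": ("bowel_obstruction", "icd10"),
    # procedures (CCI)
    "2NM70": ("colonoscopy", "cci"),
    "2NM71": ("colonoscopy", "cci"),
    "2NQ70": ("colonoscopy", "cci"),
    "2NQ71": ("colonoscopy", "cci"),
    "1NQ87": ("surgery", "cci"),
    "1NQ89": ("surgery", "cci"),
    "INM87": ("surgery", "cci"),
    "1NM87": ("surgery", "cci"),
    "1NM89": ("surgery", "cci"),
    "1NM91": ("surgery", "cci"),
    "3OT20": ("ct", "cci"),
}


@dataclass(frozen=True)
class CodeTable:
    """Mapping from raw ICD-10/CCI codes to milestone categories."""

    entries: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_CODES)
    )

    def __post_init__(self) -> None:
        for code, (category, _system) in self.entries.items():
            if category not in CATEGORIES:
                raise ValueError(f"code {code!r} maps to unknown category {category!r}")

    @classmethod
    def default(cls) -> "CodeTable":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path, extend_default: bool = True) -> "CodeTable":
        """Load a code table from YAML (``category: [codes...]`` or
        ``category: {system: [codes...]}``), optionally extending the default."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        entries: dict[str, tuple[str, str]] = dict(DEFAULT_CODES) if extend_default else {}
        for category, spec in raw.items():
            if isinstance(spec, Mapping):
                items = [(code, system) for system, codes in spec.items() for code in codes]
            else:
                items = [(code, "custom") for code in spec]
            for code, system in items:
                entries[str(code)] = (category, system)
        return cls(entries=entries)

    def map_code(self, raw_code: str) -> str | None:
        """Return the milestone category for ``raw_code``, or None if unlisted."""
        if not raw_code:
            raise ValueError("raw_code must be non-empty")
        hit = self.entries.get(raw_code)
        if hit is None:
            logger.debug("unlisted code %r ignored", raw_code)
            return None
        return hit[0]

    def codes_for(self, category: str) -> list[str]:
        return [c for c, (cat, _s) in self.entries.items() if cat == category]


def map_code(raw_code: str, table: CodeTable | None = None) -> str | None:
    """Module-level convenience wrapper around :meth:`CodeTable.map_code`."""
    return (table or CodeTable.default()).map_code(raw_code)


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Study window, pre/intra split and lookback settings.

    The default pre/intra cutoff is 29 Feb 2020: diagnoses on or before the
    cutoff are pre-pandemic, later ones intra-pandemic. An alternative split
    at 4 Mar 2020 (first reported provincial COVID-19 case on 5 Mar) can be
    configured instead.
    """

    study_start: date = date(2016, 1, 1)
    study_end: date = date(2020, 7, 1)
    pre_intra_cutoff: date = date(2020, 2, 29)
    lookback_days: int = 365
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.study_start < self.pre_intra_cutoff < self.study_end):
            raise ValueError("require study_start < pre_intra_cutoff < study_end")
        if self.lookback_days <= 0:
            raise ValueError("lookback_days must be positive")

    def with_cutoff(self, cutoff: date) -> "StudyConfig":
        return replace(self, pre_intra_cutoff=cutoff)


def assign_period(patients: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Label each patient pre/intra from the diagnosis date and cutoff.

    The labelling is exhaustive and exclusive: diagnosis on or before the
    cutoff is ``pre``, strictly after is ``intra``.
    """
    out = patients.copy()
    dx = pd.to_datetime(out["diagnosis_date"])
    out["period"] = np.where(dx <= pd.Timestamp(config.pre_intra_cutoff), "pre", "intra")
    return out


# ---------------------------------------------------------------------------
# Index-diagnosis selection
# ---------------------------------------------------------------------------


def select_index_diagnosis(diagnoses: Sequence, seed: int | np.random.Generator):
    """Pick one diagnosis uniformly at random among a patient's multiple
    CRC diagnoses in the study window; reproducible under ``seed``."""
    if len(diagnoses) == 0:
        raise ValueError("cannot select from an empty diagnosis list")
    if len(diagnoses) == 1:
        return diagnoses[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return diagnoses[int(rng.integers(len(diagnoses)))]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_patients(path: str | Path) -> pd.DataFrame:
    patients = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(PATIENT_COLUMNS) - set(patients.columns)
    if missing:
        raise ValueError(f"patients file missing columns: {sorted(missing)}")
    patients["diagnosis_date"] = pd.to_datetime(patients["diagnosis_date"])
    if (patients["age_at_diagnosis"] < 18).any():
        raise ValueError("cohort restricted to adults: age_at_diagnosis >= 18")
    return patients


def write_patients(patients: pd.DataFrame, path: str | Path) -> None:
    out = patients.copy()
    out["diagnosis_date"] = pd.to_datetime(out["diagnosis_date"]).dt.strftime("%Y-%m-%d")
    out[[c for c in PATIENT_COLUMNS if c in out.columns]
        + [c for c in out.columns if c not in PATIENT_COLUMNS]].to_csv(path, index=False)


def read_events(path: str | Path, code_table: CodeTable | None = None) -> pd.DataFrame:
    """Read an events table; rows carrying only a raw code get their
    category resolved through the code table (unlisted codes are kept with
    a missing category and ignored by downstream linkage, with a warning)."""
    table = code_table or CodeTable.default()
    events = pd.read_csv(path, dtype={"patient_id": str, "raw_code": str}, keep_default_na=False)
    if "patient_id" not in events.columns or "event_date" not in events.columns:
        raise ValueError("events file requires patient_id and event_date columns")
    events["event_date"] = pd.to_datetime(events["event_date"])
    for col, default in (("category", ""), ("raw_code", ""), ("blood_subtype", "none"),
                         ("setting", "ambulatory"), ("fit_result", "unknown")):
        if col not in events.columns:
            events[col] = default
        events[col] = events[col].replace("", default if col != "category" else "")
    need_map = (events["category"] == "") & (events["raw_code"] != "")
    if need_map.any():
        mapped = events.loc[need_map, "raw_code"].map(
            {c: cat for c, (cat, _s) in table.entries.items()}
        )
        n_unlisted = int(mapped.isna().sum())
        if n_unlisted:
            logger.warning("%d events carry unlisted codes; retained but "
                           "ignored by analysis", n_unlisted)
        events.loc[need_map, "category"] = mapped.fillna("")
    return events


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out["event_date"] = pd.to_datetime(out["event_date"]).dt.strftime("%Y-%m-%d")
    out[[c for c in EVENT_COLUMNS if c in out.columns]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Linkage and lookback windowing
# ---------------------------------------------------------------------------


def link_lookback(patients: pd.DataFrame, events: pd.DataFrame,
                  config: StudyConfig | None = None) -> pd.DataFrame:
    """Link each patient's milestone events within the lookback window.

    Keeps events with ``diagnosis_date - lookback_days <= event_date <=
    diagnosis_date`` (both ends inclusive). Events dated after diagnosis are
    dropped with a warning, as are events whose category could not be
    resolved. The result is sorted by patient, date, then (category,
    raw_code) for a stable tie order, and carries ``days_before_dx``.
    """
    config = config or StudyConfig()
    dx = patients[["patient_id", "diagnosis_date"]].copy()
    dx["diagnosis_date"] = pd.to_datetime(dx["diagnosis_date"])
    linked = events.merge(dx, on="patient_id", how="inner")
    linked["event_date"] = pd.to_datetime(linked["event_date"])
    offset = (linked["diagnosis_date"] - linked["event_date"]).dt.days

    n_post = int((offset < 0).sum())
    if n_post:
        logger.warning("dropping %d events dated after diagnosis", n_post)
    if (linked["category"] == "").any():
        logger.warning("dropping %d events with unresolved category",
                       int((linked["category"] == "").sum()))
    keep = (offset >= 0) & (offset <= config.lookback_days) & (linked["category"] != "")
    linked = linked.loc[keep].copy()
    linked["days_before_dx"] = offset[keep].astype(int)
    linked = linked.sort_values(
        ["patient_id", "event_date", "category", "raw_code"], kind="mergesort"
    ).reset_index(drop=True)
    return linked


def exclude_no_milestones(patients: pd.DataFrame,
                          linked: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop patients with no relevant milestone in the lookback window
    (they would otherwise skew interval estimates). Returns the retained
    cohort and the exclusion count."""
    has_events = patients["patient_id"].isin(linked["patient_id"].unique())
    n_excluded = int((~has_events).sum())
    if n_excluded:
        logger.info("excluded %d patients with no diagnostic milestones", n_excluded)
    return patients.loc[has_events].reset_index(drop=True), n_excluded


def history(linked: pd.DataFrame, patient_id: str) -> pd.DataFrame:
    """One patient's date-sorted lookback history."""
    return linked.loc[linked["patient_id"] == patient_id].reset_index(drop=True)
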