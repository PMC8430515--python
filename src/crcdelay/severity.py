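"""Hospital-based diagnosis as a severity proxy, and modified Poisson
relative-risk estimation.

A patient is flagged as hospital-diagnosed when an inpatient diagnostic
procedure (colonoscopy, surgery or CT) falls on the diagnosis date — the
stand-in for severe presentation when staging is unavailable. Relative
risks come from modified Poisson regression: a log-link Poisson GLM on the
binary outcome with a robust (HC0 sandwich) variance estimator, so
exp(coefficients) are relative risks with valid 95% CIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .registry import PROCEDURE_CATEGORIES


@dataclass(frozen=True)
class RRResult:
    term: str
    rr: float
    ci95: tuple[float, float]
    robust_se: float  # log scale
    adjusted: bool
    n: int

    def __post_init__(self) -> None:
        if not (self.ci95[0] <= self.rr <= self.ci95[1]):
            raise ValueError("CI must contain the point estimate")


def flag_hospital_diagnosis(patients: pd.DataFrame, linked: pd.DataFrame,
                            window_days: int = 0) -> pd.Series:
    """True iff an inpatient diagnostic procedure coincides with the
    diagnosis date (within ``window_days`` either side; default exact)."""
    ev = linked.loc[(linked["setting"] == "inpatient")
                    & linked["category"].isin(PROCEDURE_CATEGORIES),
                    ["patient_id", "event_date", "diagnosis_date"]]
    gap = (ev["diagnosis_date"] - ev["event_date"]).dt.days.abs()
    flagged = set(ev.loc[gap <= window_days, "patient_id"])
    out = patients["patient_id"].isin(flagged)
    out.index = patients["patient_id"]
    return out.rename("hospital_diagnosis")


def fit_modified_poisson(outcome, covariates: pd.DataFrame,
                         adjusted: bool = True) -> list[RRResult]:
    """Fit a log-link Poisson GLM to a binary outcome with HC0 sandwich
    variance; returns one RRResult per covariate (intercept omitted)."""
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    X = sm.add_constant(covariates.astype(float), has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(cov_type="HC0", maxiter=100, tol=1e-10)
    if not res.converged:
        raise RuntimeError(f"modified Poisson fit did not converge "
                           f"(iterations={res.fit_history['iteration']})")
    out = []
    for term in covariates.columns:
        beta = float(res.params[term])
        se = float(res.bse[term])
        if not math.isfinite(beta) or not math.isfinite(se):
            raise RuntimeError(f"separation or degenerate design for term {term!r}")
        out.append(RRResult(term=term, rr=math.exp(beta),
                            ci95=(math.exp(beta - 1.96 * se),
                                  math.exp(beta + 1.96 * se)),
                            robust_se=se, adjusted=adjusted, n=len(y)))
    return out


def unadjusted_rr(exposed_cases: int, exposed_n: int,
                  unexposed_cases: int, unexposed_n: int,
                  term: str = "exposure") -> RRResult:
    """Closed-form risk ratio with the robust (sandwich) CI for a 2x2 table.

    RR = (a/n1)/(b/n0); robust SE on the log scale is
    sqrt((1-p1)/(n1 p1) + (1-p0)/(n0 p0)), identical to the modified
    Poisson sandwich SE for a saturated binary-exposure model.
    """
    if min(exposed_n, unexposed_n) <= 0:
        raise ValueError("both margins must be positive")
    if min(exposed_cases, unexposed_cases) <= 0:
        raise ValueError("zero case cell: continuity handling is out of scope")
    p1 = exposed_cases / exposed_n
    p0 = unexposed_cases / unexposed_n
    rr = p1 / p0
    se = math.sqrt((1 - p1) / (exposed_n * p1) + (1 - p0) / (unexposed_n * p0))
    log_rr = math.log(rr)
    return RRResult(term=term, rr=rr,
                    ci95=(math.exp(log_rr - 1.96 * se), math.exp(log_rr + 1.96 * se)),
                    robust_se=se, adjusted=False, n=exposed_n + unexposed_n)


def build_covariates(patients: pd.DataFrame, linked: pd.DataFrame) -> pd.DataFrame:
    """Covariate frame for the severity model, indexed by patient_id:
    intra-period indicator, age in years, female indicator, any-FIT and
    any-bowel-obstruction indicators derived from the lookback history."""
    if "period" not in patients.columns:
        raise ValueError("patients need a 'period' column (run assign_period)")
    idx = pd.Index(patients["patient_id"], name="patient_id")
    fit_ids = set(linked.loc[linked["category"] == "fit", "patient_id"])
    obs_ids = set(linked.loc[linked["category"] == "bowel_obstruction", "patient_id"])
    return pd.DataFrame({
        "intra_period": (patients["period"].to_numpy() == "intra").astype(float),
        "age_years": patients["age_at_diagnosis"].to_numpy(dtype=float),
        "female": (patients["sex"].to_numpy() == "female").astype(float),
        "any_fit": idx.isin(fit_ids).astype(float),
        "bowel_obstruction": idx.isin(obs_ids).astype(float),
    }, index=idx)


def severity_analysis(patients: pd.DataFrame, linked: pd.DataFrame,
                      window_days: int = 0) -> dict[str, list[RRResult]]:
    """Unadjusted (single-covariate) and adjusted (all-covariate) relative
    risks of hospital-based diagnosis for period, age, sex, FIT and bowel
    obstruction."""
    y = flag_hospital_diagnosis(patients, linked, window_days=window_days)
    X = build_covariates(patients, linked)
    y = y.reindex(X.index).astype(float)
    unadj = []
    for term in X.columns:
        unadj.extend(fit_modified_poisson(y, X[[term]], adjusted=False))
    adj = fit_modified_poisson(y, X, adjusted=True)
    return {"unadjusted": unadj, "adjusted": adj}


def rr_table(results: dict[str, list[RRResult]]) -> pd.DataFrame:
    """Long-format table of unadjusted and adjusted RRs with 95% CIs."""
    rows = []
    for kind, items in results.items():
        for r in items:
            rows.append({"term": r.term, "estimate": kind, "rr": r.rr,
                         "ci_low": r.ci95[0], "ci_high": r.ci95[1], "n": r.n})
    return pd.DataFrame(rows)
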