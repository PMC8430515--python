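"""Diagnostic interval measurement and pre/intra-pandemic comparison.

Intervals run from the first occurrence of one milestone to the first
occurrence of another on or after it (``pairwise_interval``), or from the
earliest milestone to the diagnosis date (``total_interval``). Medians and
IQRs use linear-interpolation quantiles; 95% confidence intervals for the
median come from a seeded percentile bootstrap (default 5000 replicates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import SYMPTOM_CATEGORIES


def _resolve(series: pd.Series, category: str) -> pd.Series:
    """Categories may be pooled: 'symptom' matches any symptom/obstruction."""
    if category == "symptom":
        return series.isin(SYMPTOM_CATEGORIES)
    return series == category


def pairwise_interval(history: pd.DataFrame, from_category: str,
                      to_category: str) -> float | None:
    """Days from the first ``from_category`` event to the first
    ``to_category`` event on/after it; None if either is missing."""
    ev = history.sort_values("event_date", kind="mergesort")
    src = ev.loc[_resolve(ev["category"], from_category), "event_date"]
    if src.empty:
        return None
    start = src.iloc[0]
    dst = ev.loc[_resolve(ev["category"], to_category) & (ev["event_date"] >= start),
                 "event_date"]
    if dst.empty:
        return None
    return float((dst.iloc[0] - start).days)


def pairwise_intervals(linked: pd.DataFrame, from_category: str,
                       to_category: str) -> pd.Series:
    """Vectorized :func:`pairwise_interval` across a linked event table;
    returns one value per patient having both milestones in order."""
    ev = linked.sort_values(["patient_id", "event_date"], kind="mergesort")
    src = (ev.loc[_resolve(ev["category"], from_category)]
           .drop_duplicates("patient_id").set_index("patient_id")["event_date"])
    dst = ev.loc[_resolve(ev["category"], to_category),
                 ["patient_id", "event_date"]].copy()
    dst["start"] = dst["patient_id"].map(src)
    dst = dst.loc[dst["start"].notna() & (dst["event_date"] >= dst["start"])]
    first_dst = dst.drop_duplicates("patient_id")
    days = (first_dst["event_date"] - first_dst["start"]).dt.days.astype(float)
    days.index = first_dst["patient_id"]
    return days.rename(f"{from_category}_to_{to_category}")


def total_interval(history: pd.DataFrame, diagnosis_date) -> float:
    """Days from the earliest milestone to the diagnosis date (>= 0)."""
    if history.empty:
        raise ValueError("empty history: patient should have been excluded")
    first = pd.to_datetime(history["event_date"]).min()
    return float((pd.Timestamp(diagnosis_date) - first).days)


def total_intervals(linked: pd.DataFrame, patients: pd.DataFrame) -> pd.Series:
    """Total diagnostic interval per patient with >= 1 milestone."""
    first = linked.groupby("patient_id", observed=True)["event_date"].min()
    dx = patients.set_index("patient_id")["diagnosis_date"]
    days = (pd.to_datetime(dx.reindex(first.index)) - first).dt.days.astype(float)
    return days.rename("total_interval")


@dataclass(frozen=True)
class IntervalEstimate:
    boundary: tuple[str, str]
    period: str
    n: int
    median_days: float
    iqr_days: float
    ci95: tuple[float, float]
    n_boot: int


def median_iqr_ci(values, n_boot: int = 5000, seed: int = 0,
                  boundary: tuple[str, str] = ("", ""),
                  period: str = "") -> IntervalEstimate:
    """Sample median and IQR with a percentile-bootstrap 95% CI.

    Median uses the midpoint convention for even n; IQR is Q3 - Q1 with
    linear-interpolation quantiles. The CI is the (2.5, 97.5) percentile of
    ``n_boot`` resampled medians, seeded for reproducibility.
    """
    x = np.asarray(values, dtype=float)
    x = np.sort(x[~np.isnan(x)])  # sorting makes the resampling order-invariant
    if x.size == 0:
        raise ValueError("median_iqr_ci requires at least one value")
    med = float(np.median(x))
    q1, q3 = np.quantile(x, [0.25, 0.75])
    rng = np.random.default_rng(seed)
    # chunk the resample matrix to bound memory at large n
    boots = np.empty(n_boot)
    chunk = max(1, int(5e7) // max(x.size, 1))
    for lo in range(0, n_boot, chunk):
        hi = min(lo + chunk, n_boot)
        idx = rng.integers(0, x.size, size=(hi - lo, x.size))
        boots[lo:hi] = np.median(x[idx], axis=1)
    lo_ci, hi_ci = np.percentile(boots, [2.5, 97.5])
    return IntervalEstimate(boundary=boundary, period=period, n=int(x.size),
                            median_days=med, iqr_days=float(q3 - q1),
                            ci95=(float(lo_ci), float(hi_ci)), n_boot=n_boot)


def compare_periods(assignments_pre: pd.DataFrame, assignments_intra: pd.DataFrame,
                    detail_level: str = "detail") -> pd.DataFrame:
    """Pathway-proportion differences intra minus pre, with weighted averages.

    Sub-pathways (``detail_level`` column, default the observed milestone
    sequence) are nested within groups. Proportions are computed among
    classified patients within each period. Per group g,

        delta_g = sum_p w_p (pi_intra,p - pi_pre,p) / sum_p w_p

    over the sub-pathways p of g, weighted by pre-pandemic patient counts
    w_p. Negative values mean decline during the pandemic. Groups absent
    pre-pandemic are excluded with a warning.
    """
    if assignments_pre.empty or assignments_intra.empty:
        raise ValueError("both periods must be non-empty")

    def _props(a: pd.DataFrame):
        cls = a.loc[a["group"] != "unclassified"]
        counts = cls.groupby(["group", detail_level], observed=True).size()
        return counts, counts / counts.sum()

    counts_pre, pi_pre = _props(assignments_pre)
    _counts_intra, pi_intra = _props(assignments_intra)
    idx = counts_pre.index.union(pi_intra.index)
    pi_pre = pi_pre.reindex(idx, fill_value=0.0)
    pi_intra = pi_intra.reindex(idx, fill_value=0.0)
    w = counts_pre.reindex(idx, fill_value=0).astype(float)

    rows = []
    for group in idx.get_level_values(0).unique():
        wg = w.loc[group]
        if wg.sum() == 0:
            import logging
            logging.getLogger(__name__).warning(
                "group %r absent pre-pandemic; excluded from comparison", group)
            continue
        diff = pi_intra.loc[group] - pi_pre.loc[group]
        rows.append({"group": group,
                     "pre_share": float(pi_pre.loc[group].sum()),
                     "intra_share": float(pi_intra.loc[group].sum()),
                     "weighted_avg_difference": float((wg * diff).sum() / wg.sum())})
    return pd.DataFrame(rows).set_index("group")
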