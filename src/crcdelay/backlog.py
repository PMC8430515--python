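"""Colonoscopy capacity x yield scenario planning for the CRC diagnosis
backlog.

The engine assumes colonoscopy is the bottleneck procedure: a fraction
``colonoscopy_fraction`` of CRC patients undergo at least one colonoscopy,
and a fraction ``baseline_yield`` of monthly colonoscopies historically
yields a CRC diagnosis within 30 days. Expected diagnoses per month are
then V_m * baseline_yield / colonoscopy_fraction for a full-capacity volume
V_m; a scenario delivers V_m * capacity_multiplier * target_yield /
colonoscopy_fraction, and the cumulative backlog follows

    B_m = max(0, B_{m-1} + E_m - D_m),   B_0 = start_backlog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def monthly_yield(procedures: pd.DataFrame, diagnoses: pd.DataFrame,
                  window_days: int = 30) -> tuple[pd.Series, float]:
    """CRC diagnosis yield of procedures per calendar month.

    A procedure is credited when the same patient has a CRC diagnosis dated
    0..``window_days`` days after it (both ends inclusive). Returns the
    per-month yields (indexed by period) and their mean; months with zero
    procedures are excluded from the mean with a warning.
    """
    proc = procedures.copy()
    proc["procedure_date"] = pd.to_datetime(proc["procedure_date"])
    dx = diagnoses.copy()
    dx["diagnosis_date"] = pd.to_datetime(dx["diagnosis_date"])
    proc = proc.reset_index(drop=True)
    merged = proc.reset_index().merge(dx, on="patient_id", how="left")
    lag = (merged["diagnosis_date"] - merged["procedure_date"]).dt.days
    merged["hit"] = lag.between(0, window_days)
    proc["credited"] = (merged.groupby("index")["hit"].any()
                        .reindex(proc.index, fill_value=False))
    proc["month"] = proc["procedure_date"].dt.to_period("M")
    grp = proc.groupby("month")
    yields = grp["credited"].sum() / grp.size()
    if len(yields):
        span = pd.period_range(yields.index.min(), yields.index.max(), freq="M")
        empty = span.difference(yields.index)
        if len(empty):
            logger.warning("months with zero procedures excluded from mean "
                           "yield: %s", list(map(str, empty)))
    return yields.rename("yield"), float(yields.mean())


def expected_volumes(historical: Mapping[str, int] | pd.Series,
                     target_months: Sequence[str]) -> pd.Series:
    """Full-capacity baseline volumes: each target month inherits the count
    of the same calendar month one year earlier. Raises on a missing
    reference month."""
    hist = pd.Series(dict(historical))
    hist.index = pd.PeriodIndex(hist.index, freq="M")
    out = {}
    for m in pd.PeriodIndex(target_months, freq="M"):
        ref = m - 12
        if ref not in hist.index:
            raise KeyError(f"no reference volume for {m} (needs {ref})")
        out[m] = int(hist[ref])
    return pd.Series(out, name="baseline_volume")


@dataclass(frozen=True)
class ScenarioConfig:
    """One capacity x yield scenario over a monthly horizon."""

    capacity_multiplier: float = 1.0
    target_yield: float = 0.0166
    horizon_months: int = 9
    start_backlog: float = 0.0
    baseline_monthly_volume: float | Sequence[float] = 8000.0
    baseline_yield: float = 0.0166
    colonoscopy_fraction: float = 0.856

    def __post_init__(self) -> None:
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")
        if self.capacity_multiplier <= 0 or self.target_yield <= 0:
            raise ValueError("capacity_multiplier and target_yield must be positive")
        if self.start_backlog < 0:
            raise ValueError("start_backlog must be nonnegative")
        if not 0.0 < self.colonoscopy_fraction <= 1.0:
            raise ValueError("colonoscopy_fraction must be in (0, 1]")

    def volumes(self) -> np.ndarray:
        v = np.asarray(self.baseline_monthly_volume, dtype=float)
        if v.ndim == 0:
            v = np.full(self.horizon_months, float(v))
        if v.size != self.horizon_months:
            raise ValueError("baseline_monthly_volume length must match horizon")
        return v


@dataclass(frozen=True)
class BacklogTrajectory:
    monthly: pd.DataFrame          # expected, scenario, net_change, backlog
    clearance_month: int | None    # 1-based first month with zero backlog
    surge_pct: float               # mean % by which scenario exceeds expected

    @property
    def cleared(self) -> bool:
        return self.clearance_month is not None


def backlog_trajectory(config: ScenarioConfig) -> BacklogTrajectory:
    """Run the monthly backlog recursion for one scenario."""
    V = config.volumes()
    expected = V * config.baseline_yield / config.colonoscopy_fraction
    scenario = (V * config.capacity_multiplier * config.target_yield
                / config.colonoscopy_fraction)
    net = expected - scenario
    backlog = np.empty(config.horizon_months)
    b = config.start_backlog
    clearance = None
    for m in range(config.horizon_months):
        b = max(0.0, b + net[m])
        backlog[m] = b
        if clearance is None and b == 0.0:
            clearance = m + 1
    monthly = pd.DataFrame({
        "expected": expected, "scenario": scenario,
        "net_change": -net, "backlog": backlog,
    }, index=pd.RangeIndex(1, config.horizon_months + 1, name="month"))
    surge = 100.0 * float(np.mean(scenario / expected - 1.0))
    return BacklogTrajectory(monthly=monthly, clearance_month=clearance,
                             surge_pct=surge)


def clearance_search(capacities: Sequence[float], yields: Sequence[float],
                     config: ScenarioConfig, deadline_months: int | None = None
                     ) -> pd.DataFrame:
    """Evaluate a capacity x yield grid and flag clearing scenarios.

    Returns one row per grid point with its clearance month (NaN if never
    cleared within the horizon), whether it clears by the deadline, and
    whether it sits on the Pareto-minimal frontier (no other clearing point
    with both capacity and yield no larger, one strictly smaller).
    """
    deadline = deadline_months if deadline_months is not None else config.horizon_months
    if deadline > config.horizon_months:
        raise ValueError("deadline cannot exceed the horizon")
    rows = []
    for c in capacities:
        for y in yields:
            traj = backlog_trajectory(replace(config, capacity_multiplier=c,
                                              target_yield=y))
            cm = traj.clearance_month
            rows.append({"capacity_multiplier": c, "target_yield": y,
                         "clearance_month": np.nan if cm is None else cm,
                         "clears": cm is not None and cm <= deadline,
                         "surge_pct": traj.surge_pct,
                         "final_backlog": float(traj.monthly["backlog"].iloc[-1])})
    grid = pd.DataFrame(rows)
    clearing = grid.loc[grid["clears"]]
    frontier = []
    for i, row in clearing.iterrows():
        dominated = ((clearing["capacity_multiplier"] <= row["capacity_multiplier"])
                     & (clearing["target_yield"] <= row["target_yield"])
                     & ((clearing["capacity_multiplier"] < row["capacity_multiplier"])
                        | (clearing["target_yield"] < row["target_yield"]))).any()
        if not dominated:
            frontier.append(i)
    grid["on_frontier"] = grid.index.isin(frontier)
    return grid
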