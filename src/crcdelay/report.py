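"""End-to-end pipeline orchestration and report generation.

``run_pipeline`` executes link -> classify -> intervals -> severity ->
scenarios over a cohort (read from disk or simulated) and writes five table
groups as CSV plus optional figures: descriptive characteristics, pathway
proportions by period, an interval table, a relative-risk table, and a
scenario-grid summary, with a metadata sidecar (config hash, seed,
timestamp) so every number is regenerable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import backlog as bk
from . import intervals as iv
from . import pathways as pw
from . import registry as rg
from . import severity as sv
from .simulate import SimulationConfig, generate_cohort, generate_procedure_stream

logger = logging.getLogger(__name__)

#: Interval boundaries reported in the interval table.
REPORT_BOUNDARIES = [
    ("fit", "colonoscopy"), ("fit", "surgery"), ("fit", "ct"),
    ("blood_test", "colonoscopy"), ("blood_test", "surgery"), ("blood_test", "ct"),
    ("symptom", "colonoscopy"), ("symptom", "surgery"), ("symptom", "ct"),
]


@dataclass
class PipelineReport:
    descriptives: pd.DataFrame
    pathway_proportions: pd.DataFrame
    interval_table: pd.DataFrame
    rr_table: pd.DataFrame
    scenario_grid: pd.DataFrame
    metadata: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"descriptives": self.descriptives,
                "pathway_proportions": self.pathway_proportions,
                "interval_table": self.interval_table,
                "rr_table": self.rr_table,
                "scenario_grid": self.scenario_grid}


def _descriptives(patients: pd.DataFrame, hosp: pd.Series) -> pd.DataFrame:
    rows = []
    bands = [(18, 39), (40, 49), (50, 59), (60, 69), (70, 79), (80, 200)]
    for period, sub in patients.groupby("period"):
        n = len(sub)
        for lo, hi in bands:
            m = sub["age_at_diagnosis"].between(lo, hi)
            rows.append({"period": period, "variable": "age_band",
                         "level": f"{lo}-{hi if hi < 200 else '+'}",
                         "n": int(m.sum()), "pct": 100 * m.mean()})
        for var in ("sex", "cancer_site"):
            for level, cnt in sub[var].value_counts().items():
                rows.append({"period": period, "variable": var, "level": level,
                             "n": int(cnt), "pct": 100 * cnt / n})
        h = hosp.reindex(sub["patient_id"]).fillna(False)
        rows.append({"period": period, "variable": "hospital_diagnosis",
                     "level": "yes", "n": int(h.sum()), "pct": 100 * h.mean()})
    return pd.DataFrame(rows)


def _interval_table(linked: pd.DataFrame, patients: pd.DataFrame,
                    n_boot: int, seed: int) -> pd.DataFrame:
    rows = []
    by_period = dict(tuple(patients.groupby("period")))
    for period, sub in by_period.items():
        sub_linked = linked[linked["patient_id"].isin(set(sub["patient_id"]))]
        for i, (a, b) in enumerate(REPORT_BOUNDARIES):
            vals = iv.pairwise_intervals(sub_linked, a, b)
            if vals.empty:
                continue
            est = iv.median_iqr_ci(vals, n_boot=n_boot, seed=seed + i,
                                   boundary=(a, b), period=period)
            rows.append({"from": a, "to": b, "period": period, "n": est.n,
                         "median_days": est.median_days, "iqr_days": est.iqr_days,
                         "ci_low": est.ci95[0], "ci_high": est.ci95[1]})
        totals = iv.total_intervals(sub_linked, sub)
        if not totals.empty:
            est = iv.median_iqr_ci(totals, n_boot=n_boot, seed=seed + 99,
                                   boundary=("first_milestone", "diagnosis"),
                                   period=period)
            rows.append({"from": "first_milestone", "to": "diagnosis",
                         "period": period, "n": est.n,
                         "median_days": est.median_days, "iqr_days": est.iqr_days,
                         "ci_low": est.ci95[0], "ci_high": est.ci95[1]})
    return pd.DataFrame(rows)


def run_pipeline(patients: pd.DataFrame | None = None,
                 events: pd.DataFrame | None = None,
                 simulate: SimulationConfig | None = None,
                 study: rg.StudyConfig | None = None,
                 scenario: bk.ScenarioConfig | None = None,
                 n_boot: int = 1000,
                 out_dir: str | Path | None = None,
                 figures: bool = False) -> PipelineReport:
    """Run the full analysis; either pass tables or a simulation config."""
    study = study or rg.StudyConfig()
    if simulate is not None:
        cohort = generate_cohort(simulate)
        patients, events = cohort.patients, cohort.events
        procedures, proc_dx = generate_procedure_stream(simulate)
    elif patients is None or events is None:
        raise ValueError("provide patients+events tables or a simulation config")
    else:
        procedures = proc_dx = None

    patients = rg.assign_period(patients, study)
    linked = rg.link_lookback(patients, events, study)
    patients, n_excluded = rg.exclude_no_milestones(patients, linked)

    assignments = patients[["patient_id", "period"]].merge(
        pw.assign_pathway(linked, patients["patient_id"]), on="patient_id")
    prop_rows = []
    for period, sub in assignments.groupby("period"):
        props, classified = pw.pathway_proportions(sub)
        for group, p in props.items():
            prop_rows.append({"period": period, "group": group, "share": p,
                              "classified_fraction": classified})
    proportions = pd.DataFrame(prop_rows)

    interval_table = _interval_table(linked, patients, n_boot, study.rng_seed)

    hosp = sv.flag_hospital_diagnosis(patients, linked)
    rr = sv.rr_table(sv.severity_analysis(patients, linked))

    scenario = scenario or bk.ScenarioConfig()
    if procedures is not None and len(procedures):
        _monthly, mean_yield = bk.monthly_yield(procedures, proc_dx)
    else:
        mean_yield = scenario.baseline_yield
    grid = bk.clearance_search(
        capacities=[0.8, 1.0, 1.2, 1.4, 1.6],
        yields=[round(mean_yield * f, 6) for f in (1.0, 1.5, 2.0, 2.5)],
        config=scenario)

    descriptives = _descriptives(patients, hosp)
    meta = {
        "seed": study.rng_seed,
        "n_patients": int(len(patients)),
        "n_excluded_no_milestones": n_excluded,
        "n_boot": n_boot,
        "mean_monthly_yield": mean_yield,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config_hash": hashlib.sha256(
            yaml.safe_dump({"study": {k: str(v) for k, v in asdict(study).items()},
                            "scenario": asdict(scenario)}).encode()).hexdigest(),
    }
    report = PipelineReport(descriptives, proportions, interval_table, rr, grid, meta)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in report.tables().items():
            table.to_csv(out / f"{name}.csv", index=False)
        meta_out = dict(meta)
        meta_out.pop("timestamp")  # keep on-disk artifacts seed-deterministic
        (out / "metadata.json").write_text(json.dumps(meta_out, indent=2))
        if figures:
            _write_figures(report, out)
    return report


def _write_figures(report: PipelineReport, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    tab = report.interval_table
    pre = tab[tab["period"] == "pre"]
    labels = pre["from"] + "→" + pre["to"]
    ax.barh(labels, pre["median_days"], xerr=[pre["median_days"] - pre["ci_low"],
                                              pre["ci_high"] - pre["median_days"]])
    ax.set_xlabel("median interval (days)")
    ax.set_title("Pre-pandemic diagnostic intervals")
    fig.tight_layout()
    fig.savefig(out / "intervals.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    grid = report.scenario_grid
    pivot = grid.pivot(index="capacity_multiplier", columns="target_yield",
                       values="final_backlog")
    im = ax.imshow(pivot.to_numpy(), aspect="auto", origin="lower")
    ax.set_xticks(range(len(pivot.columns)),
                  [f"{y:.2%}" for y in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{c:.0%}" for c in pivot.index])
    ax.set_xlabel("CRC diagnosis yield")
    ax.set_ylabel("colonoscopy capacity")
    fig.colorbar(im, ax=ax, label="backlog at horizon")
    ax.set_title("Backlog under capacity × yield scenarios")
    fig.tight_layout()
    fig.savefig(out / "backlog_scenarios.png", dpi=120)
    plt.close(fig)
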