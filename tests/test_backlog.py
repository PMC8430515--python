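"""Monthly yield estimation, baseline volumes, backlog recursion and
clearance search."""

import numpy as np
import pandas as pd
import pytest

import crcdelay as cd
from crcdelay.backlog import ScenarioConfig


def _procs(dates):
    return pd.DataFrame({"patient_id": [f"s{i}" for i in range(len(dates))],
                         "procedure_date": pd.to_datetime(dates)})


class TestMonthlyYield:
    def test_simple_arithmetic(self):
        procs = _procs(["2019-01-10"] * 100)
        dx = pd.DataFrame({"patient_id": ["s0", "s1"],
                           "diagnosis_date": pd.to_datetime(["2019-01-20",
                                                             "2019-02-05"])})
        monthly, mean = cd.monthly_yield(procs, dx)
        assert monthly[pd.Period("2019-01")] == pytest.approx(0.02)
        assert mean == pytest.approx(0.02)

    def test_attribution_window_inclusive_of_day_30(self):
        procs = _procs(["2019-01-01", "2019-01-01"])
        dx = pd.DataFrame({"patient_id": ["s0", "s1"],
                           "diagnosis_date": pd.to_datetime(["2019-01-31",   # +30: in
                                                             "2019-02-01"])})  # +31: out
        monthly, _ = cd.monthly_yield(procs, dx)
        assert monthly[pd.Period("2019-01")] == pytest.approx(0.5)

    def test_diagnosis_before_procedure_not_credited(self):
        procs = _procs(["2019-01-10"])
        dx = pd.DataFrame({"patient_id": ["s0"],
                           "diagnosis_date": pd.to_datetime(["2019-01-05"])})
        _, mean = cd.monthly_yield(procs, dx)
        assert mean == 0.0

    def test_invariant_to_record_order_and_chunking(self):
        rng = np.random.default_rng(10)
        dates = pd.Timestamp("2019-01-01") + pd.to_timedelta(
            rng.integers(0, 120, 400), "D")
        procs = _procs(dates)
        hit = rng.random(400) < 0.05
        dx = pd.DataFrame({
            "patient_id": procs.loc[hit, "patient_id"],
            "diagnosis_date": procs.loc[hit, "procedure_date"]
            + pd.to_timedelta(rng.integers(0, 31, int(hit.sum())), "D")})
        m1, y1 = cd.monthly_yield(procs, dx)
        m2, y2 = cd.monthly_yield(procs.sample(frac=1.0, random_state=1),
                                  dx.sample(frac=1.0, random_state=2))
        pd.testing.assert_series_equal(m1, m2)
        assert y1 == y2


class TestExpectedVolumes:
    def test_same_calendar_month_prior_year(self):
        hist = {"2019-10": 9000, "2019-11": 8500}
        out = cd.expected_volumes(hist, ["2020-10", "2020-11"])
        assert out[pd.Period("2020-10")] == 9000
        assert out[pd.Period("2020-11")] == 8500

    def test_constant_reference_gives_constant_baseline(self):
        hist = {f"2019-{m:02d}": 7000 for m in range(1, 13)}
        out = cd.expected_volumes(hist, [f"2020-{m:02d}" for m in range(1, 13)])
        assert (out == 7000).all()

    def test_missing_reference_month_raises(self):
        with pytest.raises(KeyError):
            cd.expected_volumes({"2019-10": 9000}, ["2020-11"])


class TestBacklogTrajectory:
    def test_steady_state_at_baseline(self):
        config = ScenarioConfig(capacity_multiplier=1.0, target_yield=0.0166,
                                baseline_yield=0.0166, start_backlog=250.0,
                                horizon_months=6)
        traj = cd.backlog_trajectory(config)
        assert np.allclose(traj.monthly["backlog"], 250.0)
        assert traj.surge_pct == pytest.approx(0.0, abs=1e-12)
        assert not traj.cleared

    def test_hand_computed_recursion(self):
        config = ScenarioConfig(capacity_multiplier=1.4, target_yield=0.0332,
                                baseline_yield=0.0166, start_backlog=400.0,
                                baseline_monthly_volume=10_000,
                                colonoscopy_fraction=0.856, horizon_months=3)
        traj = cd.backlog_trajectory(config)
        assert traj.monthly["expected"].iloc[0] == pytest.approx(193.9, abs=0.05)
        assert traj.monthly["scenario"].iloc[0] == pytest.approx(543.0, abs=0.1)
        assert traj.monthly["net_change"].iloc[0] == pytest.approx(349.1, abs=0.1)
        assert traj.clearance_month == 2

    def test_capacity_below_one_matches_prefix_sum(self):
        config = ScenarioConfig(capacity_multiplier=0.8, target_yield=0.0166,
                                baseline_yield=0.0166, start_backlog=0.0,
                                baseline_monthly_volume=5000, horizon_months=8)
        traj = cd.backlog_trajectory(config)
        per_month = (5000 * 0.0166 / 0.856) * (1 - 0.8)
        expected = np.cumsum(np.full(8, per_month))
        assert np.allclose(traj.monthly["backlog"], expected)

    def test_backlog_floored_at_zero(self):
        config = ScenarioConfig(capacity_multiplier=3.0, target_yield=0.05,
                                baseline_yield=0.0166, start_backlog=10.0,
                                horizon_months=4)
        traj = cd.backlog_trajectory(config)
        assert (traj.monthly["backlog"] >= 0).all()
        assert traj.clearance_month == 1

    def test_monotone_in_capacity_and_yield(self):
        base = ScenarioConfig(start_backlog=500.0, horizon_months=9,
                              baseline_yield=0.0166, target_yield=0.0166)
        from dataclasses import replace
        final = {}
        caps = [0.8, 1.0, 1.2, 1.4]
        ylds = [0.0166, 0.0249, 0.0332]
        for c in caps:
            for y in ylds:
                traj = cd.backlog_trajectory(replace(base, capacity_multiplier=c,
                                                     target_yield=y))
                final[(c, y)] = traj.monthly["backlog"].iloc[-1]
        for y in ylds:
            vals = [final[(c, y)] for c in caps]
            assert all(a >= b for a, b in zip(vals, vals[1:]))
        for c in caps:
            vals = [final[(c, y)] for y in ylds]
            assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(horizon_months=0)
        with pytest.raises(ValueError):
            ScenarioConfig(start_backlog=-1)


class TestClearanceSearch:
    def test_no_clearing_points_empty_frontier(self):
        config = ScenarioConfig(start_backlog=1e9, horizon_months=3)
        grid = cd.clearance_search([0.5, 0.8], [0.01, 0.0166], config)
        assert not grid["clears"].any()
        assert not grid["on_frontier"].any()

    def test_single_clearing_point_is_the_frontier(self):
        config = ScenarioConfig(start_backlog=100.0, horizon_months=6,
                                baseline_monthly_volume=5000)
        grid = cd.clearance_search([0.9, 2.0], [0.0166], config)
        clearing = grid[grid["clears"]]
        assert len(clearing) == 1
        assert clearing["on_frontier"].all()

    def test_frontier_is_an_antichain_and_clearance_monotone(self):
        config = ScenarioConfig(start_backlog=400.0, horizon_months=9,
                                baseline_monthly_volume=8000)
        grid = cd.clearance_search([1.0, 1.2, 1.4, 1.6],
                                   [0.0166, 0.0249, 0.0332], config)
        # adding capacity or yield never removes clearance
        for _, row in grid[grid["clears"]].iterrows():
            better = grid[(grid["capacity_multiplier"] >= row["capacity_multiplier"])
                          & (grid["target_yield"] >= row["target_yield"])]
            assert better["clears"].all()
        front = grid[grid["on_frontier"]]
        for _, a in front.iterrows():
            for _, b in front.iterrows():
                if (a["capacity_multiplier"], a["target_yield"]) == \
                   (b["capacity_multiplier"], b["target_yield"]):
                    continue
                assert not (a["capacity_multiplier"] <= b["capacity_multiplier"]
                            and a["target_yield"] <= b["target_yield"])

    def test_deadline_beyond_horizon_rejected(self):
        config = ScenarioConfig(horizon_months=3)
        with pytest.raises(ValueError):
            cd.clearance_search([1.0], [0.02], config, deadline_months=5)
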