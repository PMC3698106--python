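"""EQ sweeps, travel reporting and scenario comparison."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hosplan.domain import Instance, UtilizationMode
from hosplan.instance_gen import make_micro_instance
from hosplan.optimizer import SolveOptions, solve
from hosplan.scenarios import (
    compare_landscapes,
    eq_sweep,
    travel_report,
)

from conftest import line_instance

EXACT = SolveOptions(mip_gap=1e-9)


class TestSweep:
    def test_zero_slope_instance_is_eq_invariant(self):
        inst = make_micro_instance(seed=5, n_zips=4, n_sites=3, n_groups=2,
                                   vo_categories=["none", "none"])
        res = eq_sweep(inst, [20_000.0, 50_000.0, 100_000.0], options=EXACT)
        assert np.all(res.n_locations[:, 0] == res.n_locations[:, 1])
        assert np.all(res.n_locations[:, 1] == res.n_locations[:, 2])

    def test_single_value_reduces_to_plain_solve(self):
        inst = make_micro_instance(seed=6, n_zips=4, n_sites=3, n_groups=2)
        res = eq_sweep(inst, [inst.config.euros_per_qaly], options=EXACT)
        direct = solve(inst, options=EXACT)
        assert res.objectives[0] == pytest.approx(direct.objective_eur, rel=1e-9)
        np.testing.assert_array_equal(res.n_locations[:, 0], direct.n_locations)

    def test_quality_qaly_non_decreasing_in_eq(self):
        inst = make_micro_instance(seed=7, n_zips=6, n_sites=4, n_groups=1,
                                   vo_categories=["high"],
                                   reference_gain_qaly=0.02)
        res = eq_sweep(inst, [20_000.0, 50_000.0, 100_000.0], options=EXACT)
        q = res.quality_qaly
        assert q[0] <= q[1] + 1e-9 and q[1] <= q[2] + 1e-9

    def test_tidy_frame_shape(self):
        inst = make_micro_instance(seed=8, n_zips=3, n_sites=2, n_groups=2)
        res = eq_sweep(inst, [30_000.0, 60_000.0], options=EXACT)
        df = res.to_frame()
        assert len(df) == 2 * 2
        assert set(df.columns) == {"group_id", "eq", "n_locations"}


class TestTravelReport:
    def test_single_zip_mean_is_its_travel_time(self):
        inst = line_instance(xs=(0.0, 12.0), pops=(100.0, 1e-9))
        sol = solve(inst, options=EXACT)
        rep = travel_report(inst, sol)
        # all (weighted) demand sits at the co-located site: zero minutes
        assert rep.mean_minutes["overall"] == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_class_means(self):
        inst = make_micro_instance(seed=9, n_zips=4, n_sites=2, n_groups=2)
        sol = solve(inst, options=EXACT)
        rep = travel_report(inst, sol)
        tt = inst.travel.minutes
        num = den = 0.0
        for d, g in enumerate(inst.groups):
            w = inst.demand[:, d] * g.n_visits
            minutes = tt[np.arange(inst.n_zips), sol.assign[:, d]]
            num += (w * minutes).sum()
            den += w.sum()
        assert rep.mean_minutes["overall"] == pytest.approx(num / den)

    def test_baseline_never_longer_than_solution(self):
        inst = make_micro_instance(seed=10, n_zips=5, n_sites=3, n_groups=2)
        sol = solve(inst, options=EXACT)
        rep = travel_report(inst, sol)
        ok = rep.baseline_minutes <= rep.mean_minutes + 1e-9
        assert ok[rep.weights > 0].all()

    def test_overall_is_weighted_average_of_classes(self):
        inst = make_micro_instance(seed=11, n_zips=5, n_sites=3, n_groups=3)
        sol = solve(inst, options=EXACT)
        rep = travel_report(inst, sol)
        classes = [c for c in rep.mean_minutes.index if c != "overall"]
        w = rep.weights[classes]
        m = rep.mean_minutes[classes]
        mask = w > 0
        expected = (w[mask] * m[mask]).sum() / w[mask].sum()
        assert rep.mean_minutes["overall"] == pytest.approx(expected)


class TestCompare:
    def test_single_solution_single_scenario(self):
        inst = make_micro_instance(seed=12, n_zips=3, n_sites=2, n_groups=2)
        sol = solve(inst, options=EXACT)
        df = compare_landscapes(inst, {"base": sol})
        assert set(df["scenario"]) == {"base"}
        assert len(df) == inst.n_groups + 1  # per-group rows + total

    def test_identical_solutions_identical_columns(self):
        inst = make_micro_instance(seed=13, n_zips=3, n_sites=2, n_groups=2)
        sol = solve(inst, options=EXACT)
        df = compare_landscapes(inst, [("a", sol), ("b", sol)])
        a = df[df.scenario == "a"].drop(columns="scenario").reset_index(drop=True)
        b = df[df.scenario == "b"].drop(columns="scenario").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_labels_rejected(self):
        inst = make_micro_instance(seed=13, n_zips=3, n_sites=2, n_groups=2)
        sol = solve(inst, options=EXACT)
        with pytest.raises(ValueError):
            compare_landscapes(inst, [("a", sol), ("a", sol)])

    def test_conditional_mode_dominates_literal(self):
        inst = make_micro_instance(seed=14, n_zips=4, n_sites=3, n_groups=2,
                                   with_minima=True)
        sols = {}
        for mode in ("conditional", "literal"):
            cfg = dataclasses.replace(inst.config,
                                      utilization_mode=UtilizationMode(mode))
            inst_m = Instance(groups=inst.groups, zips=inst.zips,
                              sites=inst.sites, travel=inst.travel,
                              demand=inst.demand,
                              quality_functions=inst.quality_functions,
                              colocate_pairs=inst.colocate_pairs, config=cfg)
            sols[mode] = solve(inst_m, options=EXACT)
        if sols["literal"].solver_status.value == "optimal":
            df = compare_landscapes(inst, sols)
            tot = df[df.group_id == "total"].set_index("scenario")
            assert (tot.loc["conditional", "objective_eur"]
                    >= tot.loc["literal", "objective_eur"] - 1e-6)
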