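"""MIP construction, solving, travel accounting and the refinement loop."""

import dataclasses

import numpy as np
import pytest

from hosplan.domain import (
    Facility,
    FacilityType,
    Instance,
    SolverStatus,
    validate_solution,
)
from hosplan.instance_gen import make_micro_instance
from hosplan.optimizer import (
    SolveOptions,
    UncoveredDemandError,
    build_model,
    compute_travel_eur,
    solve,
    solve_with_refinement,
)
from hosplan.oracle import enumerate_optimum, nearest_feasible_assignment

from conftest import (
    SEGMENTS_CYCLE,
    SEGMENTS_FIXED_POINT,
    line_instance,
    tiny_instance,
)

EXACT = SolveOptions(mip_gap=1e-9)


def _active(inst):
    return {g.id: inst.quality_functions[g.id].segments[0] for g in inst.groups}


class TestBuildModel:
    def test_minimal_variable_count(self):
        inst = tiny_instance()
        spec = build_model(inst, _active(inst))
        assert spec.n_vars == 3  # one X, one Z, one Y
        assert len(spec.y_keys) == 1

    def test_travel_limit_restricts_y_domain(self):
        inst = line_instance(xs=(0.0, 50.0), max_travel_min=45.0)
        spec = build_model(inst, _active(inst))
        # each zip may only reach its co-located site: 2 Y vars, not 4
        assert len(spec.y_keys) == 2

    def test_uncovered_pair_reported_before_solve(self):
        inst = line_instance(xs=(0.0, 30.0, 100.0), max_travel_min=45.0)
        # move all sites away from the last zip
        inst.sites = inst.sites[:2]
        inst.travel = dataclasses.replace(
            inst.travel, minutes=inst.travel.minutes[:, :2])
        with pytest.raises(UncoveredDemandError) as err:
            build_model(inst, _active(inst))
        assert ("z2", 1) in err.value.uncovered

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_tight_and_bigm_linking_agree(self, seed):
        inst = make_micro_instance(seed=seed, n_zips=4, n_sites=3, n_groups=2,
                                   with_minima=(seed % 2 == 0))
        sols = [
            solve(inst, options=SolveOptions(mip_gap=1e-9, linking_mode=mode))
            for mode in ("tight", "big_m")
        ]
        assert sols[0].solver_status is SolverStatus.OPTIMAL
        assert sols[0].objective_eur == pytest.approx(sols[1].objective_eur,
                                                      rel=1e-6)


class TestSolve:
    def test_forced_single_configuration(self):
        inst = tiny_instance()
        sol = solve(inst, options=EXACT)
        assert sol.solver_status is SolverStatus.OPTIMAL
        assert sol.open_sites.tolist() == [1]
        assert sol.offers.tolist() == [[1]]
        assert sol.n_locations.tolist() == [1]
        assert validate_solution(inst, sol) == []

    def test_positive_travel_cost_prefers_near_site(self):
        inst = line_instance(xs=(0.0, 20.0), pops=(100.0, 1e-6))
        sol = solve(inst, options=EXACT)
        # all demand sits at x=0; it must be served by the co-located site
        assert sol.assign[0, 0] == 0

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_oracle_on_micro_instances(self, seed):
        inst = make_micro_instance(seed=seed, n_zips=4, n_sites=3, n_groups=2)
        sol = solve(inst, options=EXACT)
        ref = enumerate_optimum(inst)
        assert sol.objective_eur == pytest.approx(ref.objective_eur, rel=1e-6)
        assert validate_solution(inst, sol) == []

    def test_infeasible_reports_uncovered_pairs(self):
        inst = line_instance(xs=(0.0, 100.0), max_travel_min=45.0)
        inst.sites = inst.sites[:1]
        inst.travel = dataclasses.replace(
            inst.travel, minutes=inst.travel.minutes[:, :1])
        sol = solve(inst, options=EXACT)
        assert sol.solver_status is SolverStatus.INFEASIBLE
        assert ("z1", 1) in sol.diagnostics["uncovered"]


class TestTravelEuros:
    def test_hand_example(self):
        # 10 patients, NV=2, TT=30 min, ET=60 €/h -> 2*60*2*10*0.5 = 1200 €
        inst = tiny_instance(tt_min=30.0, maxt=45.0)
        cfg = dataclasses.replace(inst.config, euros_per_travel_hour=60.0)
        inst = Instance(groups=inst.groups, zips=inst.zips, sites=inst.sites,
                        travel=inst.travel, demand=inst.demand,
                        quality_functions=inst.quality_functions,
                        colocate_pairs=[], config=cfg)
        assign = np.array([[0]])
        assert compute_travel_eur(inst, assign, 1) == pytest.approx(1200.0)

    def test_zero_travel_time(self):
        inst = tiny_instance(tt_min=0.0)
        assert compute_travel_eur(inst, np.array([[0]]), 1) == 0.0

    def test_linear_in_visits(self):
        inst = make_micro_instance(seed=1, n_zips=3, n_sites=2, n_groups=1)
        assign = nearest_feasible_assignment(
            inst, np.ones((inst.n_sites, 1), dtype=np.int8))
        base = compute_travel_eur(inst, assign, 1)
        doubled = [dataclasses.replace(g, n_visits=2 * g.n_visits)
                   for g in inst.groups]
        inst2 = Instance(groups=doubled, zips=inst.zips, sites=inst.sites,
                         travel=inst.travel, demand=inst.demand,
                         quality_functions=inst.quality_functions,
                         colocate_pairs=[], config=inst.config)
        assert compute_travel_eur(inst2, assign, 1) == pytest.approx(2 * base)


class TestRefinement:
    def test_single_segment_is_one_iteration(self):
        inst = make_micro_instance(seed=2, n_zips=4, n_sites=3, n_groups=2)
        direct = solve(inst, options=EXACT)
        sol, trace = solve_with_refinement(inst, options=EXACT)
        assert len(trace) == 1 and trace.converged
        assert sol.objective_eur == pytest.approx(direct.objective_eur, rel=1e-9)

    def test_two_segment_fixed_point(self):
        inst = line_instance(segments=SEGMENTS_FIXED_POINT)
        sol, trace = solve_with_refinement(inst, options=EXACT)
        assert trace.converged and not trace.cycle_detected
        assert len(trace) == 2
        nl = int(sol.n_locations[0])
        assert nl == 1
        active_key = trace.iterations[-1]["active"]
        seg = inst.quality_functions[1].segments[active_key[0][1]]
        assert seg.contains(nl)

    def test_cycle_returns_best_true_objective(self):
        inst = line_instance(segments=SEGMENTS_CYCLE)
        sol, trace = solve_with_refinement(inst, options=EXACT)
        assert trace.cycle_detected and not trace.converged
        assert len(trace) <= inst.config.max_refinement_iters
        # candidates visited: 1 location (true objective 8000 €) and
        # 5 locations (0 €); the better one must come back
        assert int(sol.n_locations[0]) == 1
        assert sol.objective_eur == pytest.approx(8000.0, rel=1e-6)


class TestStructuralProperties:
    @pytest.mark.parametrize("seed", [20, 21])
    def test_tightening_travel_limit_never_helps(self, seed):
        inst = make_micro_instance(seed=seed, n_zips=5, n_sites=3, n_groups=2)
        base = solve(inst, options=EXACT)
        tt = inst.travel.minutes
        tighter = []
        for g in inst.groups:
            floor = float(tt.min(axis=1).max()) + 1.0  # keep coverage
            tighter.append(dataclasses.replace(
                g, max_travel_min=max(0.6 * g.max_travel_min, floor)))
        inst2 = Instance(groups=tighter, zips=inst.zips, sites=inst.sites,
                         travel=inst.travel, demand=inst.demand,
                         quality_functions=inst.quality_functions,
                         colocate_pairs=inst.colocate_pairs, config=inst.config)
        tight = solve(inst2, options=EXACT)
        assert tight.solver_status is SolverStatus.OPTIMAL
        assert tight.objective_eur <= base.objective_eur + 1e-6 * abs(base.objective_eur)

    @pytest.mark.parametrize("seed", [22, 23])
    def test_dropping_minima_never_hurts(self, seed):
        inst = make_micro_instance(seed=seed, n_zips=4, n_sites=3, n_groups=2,
                                   with_minima=True)
        constrained = solve(inst, options=EXACT)
        relaxed_cfg = dataclasses.replace(
            inst.config, facilities=tuple(Facility(f, 0.0) for f in FacilityType))
        inst2 = Instance(groups=inst.groups, zips=inst.zips, sites=inst.sites,
                         travel=inst.travel, demand=inst.demand,
                         quality_functions=inst.quality_functions,
                         colocate_pairs=inst.colocate_pairs, config=relaxed_cfg)
        relaxed = solve(inst2, options=EXACT)
        if constrained.solver_status is SolverStatus.OPTIMAL:
            assert relaxed.objective_eur >= constrained.objective_eur - 1e-6 * abs(
                constrained.objective_eur)

    def test_zero_slope_limit_reproduces_nearest_assignment(self):
        inst = line_instance()  # flat quality, no minima, generous limit
        sol = solve(inst, options=EXACT)
        # optimal travel equals the all-sites-open nearest-site bound (zero
        # on this geometry: every zip hosts a site)
        assert sol.travel_eur.sum() == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_array_equal(sol.assign[:, 0], np.arange(5))
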