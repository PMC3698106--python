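"""The mixed-integer allocation model and its piecewise refinement loop.

The model opens sites (X_q), offers diagnosis groups at sites (Z_{q,d}) and
assigns each zip's demand per group to exactly one site (Y_{p,q,d}),
maximizing monetized quality minus travel cost:

    max  sum_d [ EQ * NP_d * (a_d * NL_d + b_d)
                 - rt * ET * NV_d * sum_{p,q} NPD_{p,d} * Y_{p,q,d} * TT_{p,q} / 60 ]

with NL_d = sum_q Z_{q,d}, travel-time caps enforced by restricting the Y
domain to pairs within each group's maximum, linking Y <= Z <= X (tight
per-pair by default; the aggregated big-M forms are available for fidelity),
minimum facility utilization at open sites, and co-location ties between
configured group pairs.

Quality is piecewise linear in NL_d; each solve linearizes with one active
segment per group and the outer refinement loop re-selects segments until the
realized location counts fall inside their active intervals.

The solver backend is an abstract ``ModelSpec`` (objective vector, sparse
linear constraints, binary integrality) handed to a MILP engine; the bundled
backend uses HiGHS via :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .calibration import evaluate_quality_eur
from .domain import (
    FacilityType,
    Instance,
    QualityFunction,
    QualitySegment,
    Solution,
    SolverStatus,
    UtilizationMode,
)

__all__ = [
    "SolveOptions",
    "LinkingMode",
    "ModelSpec",
    "UncoveredDemandError",
    "RefinementTrace",
    "build_model",
    "solve_model_spec",
    "solve",
    "solve_with_refinement",
    "compute_travel_eur",
]


class UncoveredDemandError(ValueError):
    """Some zip-group pair has no candidate site within its travel limit; the
    model is infeasible before any solve."""

    def __init__(self, uncovered: List[Tuple[str, int]]):
        self.uncovered = uncovered
        preview = ", ".join(f"(zip {p}, group {d})" for p, d in uncovered[:5])
        more = "" if len(uncovered) <= 5 else f" and {len(uncovered) - 5} more"
        super().__init__(f"uncovered demand: {preview}{more}")


@dataclass(frozen=True)
class SolveOptions:
    """Solver controls.  ``linking_mode='tight'`` uses per-pair linking
    constraints (same feasible set as the aggregated big-M forms, far stronger
    LP relaxation); ``'big_m'`` reproduces the aggregated forms."""

    time_limit_s: float = 600.0
    mip_gap: float = 1e-6
    linking_mode: str = "tight"
    threads: int = 1
    log_level: int = 0

    def __post_init__(self) -> None:
        if self.mip_gap < 0:
            raise ValueError("mip_gap must be >= 0")
        if self.linking_mode not in ("tight", "big_m"):
            raise ValueError("linking_mode must be 'tight' or 'big_m'")


LinkingMode = str  # 'tight' | 'big_m'


@dataclass
class ModelSpec:
    """Solver-agnostic MILP description (all variables binary, maximize c@x).

    Variable layout: X (n_sites), then Z (site-major, n_sites*n_groups), then
    one Y per admissible (zip, site, group) triple, then, in conditional
    utilization mode, one facility-present binary W per (site, facility).
    """

    c: np.ndarray                       # maximize
    constant: float                     # objective constant (intercept terms)
    A_eq: sp.csr_matrix
    b_eq: np.ndarray
    A_ub: sp.csr_matrix                 # A_ub @ x <= b_ub
    b_ub: np.ndarray
    n_sites: int
    n_groups: int
    y_keys: List[Tuple[int, int, int]]  # (p, q, d) per Y variable
    w_keys: List[Tuple[int, FacilityType]] = field(default_factory=list)

    @property
    def n_vars(self) -> int:
        return self.c.size

    @property
    def n_constraints(self) -> int:
        return self.A_eq.shape[0] + self.A_ub.shape[0]

    def x_index(self, q: int) -> int:
        return q

    def z_index(self, q: int, d: int) -> int:
        return self.n_sites + q * self.n_groups + d


def _allowed_sites(instance: Instance) -> List[List[np.ndarray]]:
    """allowed[d] = array of site indices within group d's travel limit, per zip."""
    tt = instance.travel.minutes
    out: List[List[np.ndarray]] = []
    for g in instance.groups:
        ok = tt <= g.max_travel_min + 1e-9
        out.append([np.nonzero(ok[p])[0] for p in range(instance.n_zips)])
    return out


def build_model(
    instance: Instance,
    active_segments: Mapping[int, QualitySegment],
    options: Optional[SolveOptions] = None,
) -> ModelSpec:
    """Assemble the MILP for one linearization (one active quality segment per
    group).  Raises :class:`UncoveredDemandError`, naming the uncovered
    zip-group pairs, if some zip has no admissible site for some group."""
    options = options or SolveOptions()
    cfg = instance.config
    nZ, nS, nG = instance.n_zips, instance.n_sites, instance.n_groups
    tt = instance.travel.minutes
    allowed = _allowed_sites(instance)

    uncovered = [
        (instance.zips[p].id, instance.groups[d].id)
        for d in range(nG)
        for p in range(nZ)
        if allowed[d][p].size == 0
    ]
    if uncovered:
        raise UncoveredDemandError(uncovered)

    y_keys: List[Tuple[int, int, int]] = []
    y_index: Dict[Tuple[int, int, int], int] = {}
    n_xz = nS + nS * nG
    for d in range(nG):
        for p in range(nZ):
            for q in allowed[d][p]:
                y_index[(p, int(q), d)] = n_xz + len(y_keys)
                y_keys.append((p, int(q), d))
    nY = len(y_keys)

    conditional = cfg.utilization_mode is UtilizationMode.CONDITIONAL
    minus = {f: cfg.min_utilization(f) for f in FacilityType}
    active_fac = [f for f in FacilityType if minus[f] > 0]
    w_keys: List[Tuple[int, FacilityType]] = []
    w_index: Dict[Tuple[int, FacilityType], int] = {}
    if conditional and active_fac:
        for q in range(nS):
            for f in active_fac:
                w_index[(q, f)] = n_xz + nY + len(w_keys)
                w_keys.append((q, f))
    n_vars = n_xz + nY + len(w_keys)

    # ---- objective (maximize) -------------------------------------------
    c = np.zeros(n_vars)
    constant = 0.0

    def z_idx(q: int, d: int) -> int:
        return nS + q * nG + d

    for d, g in enumerate(instance.groups):
        seg = active_segments[g.id]
        c[[z_idx(q, d) for q in range(nS)]] += cfg.euros_per_qaly * g.n_patients * seg.slope
        constant += cfg.euros_per_qaly * g.n_patients * seg.intercept
    travel_coef = np.empty(nY)
    for i, (p, q, d) in enumerate(y_keys):
        g = instance.groups[d]
        travel_coef[i] = (
            cfg.round_trip_factor
            * cfg.euros_per_travel_hour
            * g.n_visits
            * instance.demand[p, d]
            * tt[p, q]
            / 60.0
        )
    c[n_xz:n_xz + nY] = -travel_coef

    # ---- constraints -----------------------------------------------------
    eq_rows, eq_cols, eq_vals, b_eq = [], [], [], []
    ub_rows, ub_cols, ub_vals, b_ub = [], [], [], []

    def add_eq(cols, vals, rhs):
        r = len(b_eq)
        eq_rows.extend([r] * len(cols))
        eq_cols.extend(cols)
        eq_vals.extend(vals)
        b_eq.append(rhs)

    def add_ub(cols, vals, rhs):
        r = len(b_ub)
        ub_rows.extend([r] * len(cols))
        ub_cols.extend(cols)
        ub_vals.extend(vals)
        b_ub.append(rhs)

    # completeness: every zip-group pair served by exactly one admissible site
    for d in range(nG):
        for p in range(nZ):
            cols = [y_index[(p, int(q), d)] for q in allowed[d][p]]
            add_eq(cols, [1.0] * len(cols), 1.0)

    # linking
    if options.linking_mode == "tight":
        for (p, q, d), yi in y_index.items():
            add_ub([yi, z_idx(q, d)], [1.0, -1.0], 0.0)
        for q in range(nS):
            for d in range(nG):
                add_ub([z_idx(q, d), q], [1.0, -1.0], 0.0)
    else:  # aggregated big-M forms
        M = cfg.big_m
        by_qd: Dict[Tuple[int, int], List[int]] = {}
        for (p, q, d), yi in y_index.items():
            by_qd.setdefault((q, d), []).append(yi)
        for (q, d), yis in by_qd.items():
            add_ub(yis + [z_idx(q, d)], [1.0] * len(yis) + [-M], 0.0)
        for q in range(nS):
            cols = [z_idx(q, d) for d in range(nG)] + [q]
            add_ub(cols, [1.0] * nG + [-M], 0.0)

    # minimum facility utilization
    usage_cols: Dict[Tuple[int, FacilityType], List[int]] = {}
    usage_vals: Dict[Tuple[int, FacilityType], List[float]] = {}
    if active_fac:
        for i, (p, q, d) in enumerate(y_keys):
            g = instance.groups[d]
            for f in active_fac:
                u = g.usage[f] * instance.demand[p, d]
                if u > 0:
                    usage_cols.setdefault((q, f), []).append(n_xz + i)
                    usage_vals.setdefault((q, f), []).append(u)
        if conditional:
            caps = {
                f: sum(g.n_patients * g.usage[f] for g in instance.groups) + 1.0
                for f in active_fac
            }
            for q in range(nS):
                for f in active_fac:
                    cols = usage_cols.get((q, f), [])
                    vals = usage_vals.get((q, f), [])
                    wi = w_index[(q, f)]
                    # usage >= minu * W   (facility absent or efficient)
                    add_ub(cols + [wi], [-v for v in vals] + [minus[f]], 0.0)
                    # usage <= cap * W    (no usage without the facility)
                    add_ub(cols + [wi], list(vals) + [-caps[f]], 0.0)
        else:  # literal: every open site meets every facility minimum
            for q in range(nS):
                for f in active_fac:
                    cols = usage_cols.get((q, f), [])
                    vals = usage_vals.get((q, f), [])
                    add_ub(cols + [q], [-v for v in vals] + [minus[f]], 0.0)

    # co-location: tied groups offered at identical site sets
    for g1, g2 in instance.colocate_pairs:
        d1, d2 = instance.group_index(g1), instance.group_index(g2)
        for q in range(nS):
            add_eq([z_idx(q, d1), z_idx(q, d2)], [1.0, -1.0], 0.0)

    A_eq = sp.csr_matrix(
        (eq_vals, (eq_rows, eq_cols)), shape=(len(b_eq), n_vars))
    A_ub = sp.csr_matrix(
        (ub_vals, (ub_rows, ub_cols)), shape=(len(b_ub), n_vars))
    return ModelSpec(
        c=c,
        constant=constant,
        A_eq=A_eq,
        b_eq=np.array(b_eq),
        A_ub=A_ub,
        b_ub=np.array(b_ub),
        n_sites=nS,
        n_groups=nG,
        y_keys=y_keys,
        w_keys=w_keys,
    )


def solve_model_spec(
    spec: ModelSpec, options: SolveOptions
) -> Tuple[Optional[np.ndarray], SolverStatus, float]:
    """Backend contract: solve a ModelSpec, return (values, status, gap).
    This implementation uses HiGHS through scipy."""
    constraints = []
    if spec.A_eq.shape[0]:
        constraints.append(LinearConstraint(spec.A_eq, spec.b_eq, spec.b_eq))
    if spec.A_ub.shape[0]:
        constraints.append(LinearConstraint(spec.A_ub, -np.inf, spec.b_ub))
    res = milp(
        -spec.c,  # scipy minimizes
        constraints=constraints,
        integrality=np.ones(spec.n_vars),
        bounds=Bounds(0.0, 1.0),
        options={
            "disp": options.log_level > 1,
            "mip_rel_gap": options.mip_gap,
            "time_limit": options.time_limit_s,
        },
    )
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    if res.status == 0:
        return np.asarray(res.x), SolverStatus.OPTIMAL, gap
    if res.status == 1 and res.x is not None:
        return np.asarray(res.x), SolverStatus.FEASIBLE, gap
    if res.status == 2:
        return None, SolverStatus.INFEASIBLE, math.inf
    return None, SolverStatus.ERROR, math.inf


def compute_travel_eur(instance: Instance, assign: np.ndarray, group_id: int) -> float:
    """Annual travel cost for one group under an assignment:
    rt * ET * NV_d * sum_p NPD_{p,d} * TT_{p, assign(p)} / 60  (minutes → hours)."""
    cfg = instance.config
    d = instance.group_index(group_id)
    g = instance.groups[d]
    a = assign[:, d]
    mask = a >= 0
    minutes = instance.travel.minutes[np.nonzero(mask)[0], a[mask]]
    return float(
        cfg.round_trip_factor
        * cfg.euros_per_travel_hour
        * g.n_visits
        * np.sum(instance.demand[mask, d] * minutes)
        / 60.0
    )


def _extract_solution(
    instance: Instance,
    spec: ModelSpec,
    values: np.ndarray,
    status: SolverStatus,
    gap: float,
) -> Solution:
    nZ, nS, nG = instance.n_zips, instance.n_sites, instance.n_groups
    x = (values[:nS] > 0.5).astype(np.int8)
    z = np.zeros((nS, nG), dtype=np.int8)
    zvals = values[nS:nS + nS * nG].reshape(nS, nG)
    z[zvals > 0.5] = 1
    assign = -np.ones((nZ, nG), dtype=np.int64)
    n_xz = nS + nS * nG
    yv = values[n_xz:n_xz + len(spec.y_keys)]
    # pick, per (p,d), the admissible site with the largest Y value
    best = np.full((nZ, nG), -1.0)
    for i, (p, q, d) in enumerate(spec.y_keys):
        if yv[i] > best[p, d]:
            best[p, d] = yv[i]
            assign[p, d] = q
    assign[best < 0.5] = -1

    nl = z.sum(axis=0)
    quality = np.array([
        evaluate_quality_eur(
            g, instance.quality_functions[g.id], int(nl[d]),
            instance.config.euros_per_qaly)
        if nl[d] >= 1 else 0.0
        for d, g in enumerate(instance.groups)
    ])
    travel = np.array([
        compute_travel_eur(instance, assign, g.id) for g in instance.groups
    ])
    return Solution(
        open_sites=x,
        offers=z,
        assign=assign,
        n_locations=nl,
        quality_eur=quality,
        travel_eur=travel,
        objective_eur=float(np.sum(quality - travel)),
        solver_status=status,
        gap=gap,
    )


def _default_active_segments(
    instance: Instance, baseline_nl: Optional[int] = None
) -> Dict[int, QualitySegment]:
    """Initial linearization: for each group the segment containing the
    status-quo location count (clipped into the function's domain)."""
    out = {}
    for g in instance.groups:
        qf = instance.quality_functions[g.id]
        nl0 = baseline_nl if baseline_nl is not None else qf.nl_max
        nl0 = min(max(nl0, qf.nl_min), qf.nl_max)
        out[g.id] = qf.segment_for(nl0)
    return out


def _infeasible_solution(instance: Instance, diagnostics: dict) -> Solution:
    nZ, nS, nG = instance.n_zips, instance.n_sites, instance.n_groups
    return Solution(
        open_sites=np.zeros(nS, dtype=np.int8),
        offers=np.zeros((nS, nG), dtype=np.int8),
        assign=-np.ones((nZ, nG), dtype=np.int64),
        n_locations=np.zeros(nG, dtype=np.int64),
        quality_eur=np.zeros(nG),
        travel_eur=np.zeros(nG),
        objective_eur=-math.inf,
        solver_status=SolverStatus.INFEASIBLE,
        gap=math.inf,
        diagnostics=diagnostics,
    )


def solve(
    instance: Instance,
    options: Optional[SolveOptions] = None,
    active_segments: Optional[Mapping[int, QualitySegment]] = None,
) -> Solution:
    """Build and solve one linearization of the model.

    Quality and travel components of the returned solution are recomputed from
    Y/Z by this module's own formulas (quality from the full piecewise
    function at the realized NL_d), never trusted from the solver.  An
    infeasible model yields a Solution with status ``infeasible``; when the
    cause is an uncovered zip-group pair the diagnosis is attached under
    ``diagnostics['uncovered']``.
    """
    options = options or SolveOptions(mip_gap=instance.config.mip_gap)
    segs = dict(active_segments) if active_segments else _default_active_segments(instance)
    try:
        spec = build_model(instance, segs, options)
    except UncoveredDemandError as exc:
        return _infeasible_solution(instance, {"uncovered": exc.uncovered})
    values, status, gap = solve_model_spec(spec, options)
    if values is None:
        return _infeasible_solution(instance, {"solver": status.value})
    sol = _extract_solution(instance, spec, values, status, gap)
    sol.diagnostics["model_size"] = {
        "variables": spec.n_vars, "constraints": spec.n_constraints}
    return sol


@dataclass
class RefinementTrace:
    """Per-iteration record of the outer segment-selection loop."""

    iterations: List[dict] = field(default_factory=list)
    converged: bool = False
    cycle_detected: bool = False

    def __len__(self) -> int:
        return len(self.iterations)


def solve_with_refinement(
    instance: Instance,
    quality_functions: Optional[Mapping[int, QualityFunction]] = None,
    options: Optional[SolveOptions] = None,
) -> Tuple[Solution, RefinementTrace]:
    """Solve the piecewise-quality problem by iterating linearizations.

    Each iteration solves with one active segment per group, then checks
    whether every realized NL_d lies inside its active interval; if not, the
    containing segment becomes active and the model is re-solved.  The loop
    stops at a fixed point, on a detected cycle, or at the iteration cap; in
    the latter two cases the visited solution with the best true piecewise
    objective is returned (never an exception).
    """
    if quality_functions is not None:
        qfs = dict(quality_functions)
        instance = Instance(
            groups=instance.groups,
            zips=instance.zips,
            sites=instance.sites,
            travel=instance.travel,
            demand=instance.demand,
            quality_functions=qfs,
            colocate_pairs=instance.colocate_pairs,
            config=instance.config,
        )
    qfs = instance.quality_functions
    trace = RefinementTrace()
    active = _default_active_segments(instance)
    seen: Dict[Tuple[Tuple[int, int], ...], int] = {}
    best_sol: Optional[Solution] = None

    def seg_key(segs: Mapping[int, QualitySegment]) -> Tuple[Tuple[int, int], ...]:
        return tuple(
            (g.id, qfs[g.id].segments.index(segs[g.id])) for g in instance.groups
        )

    for it in range(instance.config.max_refinement_iters):
        key = seg_key(active)
        if key in seen:
            trace.cycle_detected = True
            break
        seen[key] = it
        sol = solve(instance, options=options, active_segments=active)
        if sol.solver_status in (SolverStatus.INFEASIBLE, SolverStatus.ERROR):
            trace.iterations.append({"active": key, "status": sol.solver_status.value})
            return sol, trace
        trace.iterations.append({
            "active": key,
            "nl": sol.n_locations.copy(),
            "objective_true": sol.objective_eur,
            "status": sol.solver_status.value,
        })
        if best_sol is None or sol.objective_eur > best_sol.objective_eur:
            best_sol = sol

        new_active = {}
        changed = False
        for d, g in enumerate(instance.groups):
            seg = active[g.id]
            nl = int(sol.n_locations[d])
            if nl >= 1 and not seg.contains(nl):
                cand = qfs[g.id].segment_for(nl)
                # identical line => same optimum; treat as converged for d
                if (cand.slope, cand.intercept) != (seg.slope, seg.intercept):
                    new_active[g.id] = cand
                    changed = True
                    continue
            new_active[g.id] = seg
        if not changed:
            trace.converged = True
            return sol, trace
        active = new_active

    assert best_sol is not None or trace.cycle_detected
    if best_sol is None:  # pragma: no cover - cycle on first key impossible
        raise RuntimeError("refinement produced no candidate")
    return best_sol, trace
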