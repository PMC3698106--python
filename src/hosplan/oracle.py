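"""Exhaustive-enumeration reference solver for micro instances.

Independent of the MIP machinery: it enumerates offering patterns directly
(and, when utilization minima couple the assignment, the assignments too),
scores candidates with the true piecewise objective, and certifies optimality
on instances small enough to enumerate.  Used as the correctness anchor for
the optimizer.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .calibration import evaluate_quality_eur
from .domain import (
    FacilityType,
    Instance,
    Solution,
    SolverStatus,
    UtilizationMode,
)

__all__ = [
    "OracleLimits",
    "OracleSizeError",
    "UncoveredAssignmentError",
    "nearest_feasible_assignment",
    "enumerate_optimum",
]


@dataclass(frozen=True)
class OracleLimits:
    """Enumeration guards: the oracle refuses instances beyond these sizes
    rather than running forever."""

    max_zips: int = 8
    max_sites: int = 5
    max_groups: int = 3
    max_states: int = 2_000_000

    def __post_init__(self) -> None:
        if min(self.max_zips, self.max_sites, self.max_groups, self.max_states) < 1:
            raise ValueError("all limits must be >= 1")


class OracleSizeError(ValueError):
    """The enumeration state space exceeds the configured guard."""


class UncoveredAssignmentError(ValueError):
    """Some zip-group pair has no offering site within its travel limit."""


def nearest_feasible_assignment(instance: Instance, offers: np.ndarray) -> np.ndarray:
    """Assign every zip-group pair to the offering site with minimum travel
    time (within the group's limit); ties break toward the lowest site index,
    i.e. lexicographically smallest site id.

    Raises :class:`UncoveredAssignmentError` when a pair has no admissible
    offering site.
    """
    nZ, nG = instance.n_zips, instance.n_groups
    tt = instance.travel.minutes
    assign = -np.ones((nZ, nG), dtype=np.int64)
    for d, g in enumerate(instance.groups):
        sites = np.nonzero(offers[:, d])[0]
        if sites.size == 0:
            raise UncoveredAssignmentError(f"group {g.id}: no offering site")
        for p in range(nZ):
            ok = sites[tt[p, sites] <= g.max_travel_min + 1e-9]
            if ok.size == 0:
                raise UncoveredAssignmentError(
                    f"zip {instance.zips[p].id}, group {g.id}: "
                    "no offering site within the travel limit")
            # np.argmin returns the first minimum -> lowest site index on ties
            assign[p, d] = ok[int(np.argmin(tt[p, ok]))]
    return assign


def _objective(instance: Instance, offers: np.ndarray, assign: np.ndarray
               ) -> Tuple[float, np.ndarray, np.ndarray]:
    cfg = instance.config
    tt = instance.travel.minutes
    nl = offers.sum(axis=0)
    quality = np.empty(instance.n_groups)
    travel = np.empty(instance.n_groups)
    for d, g in enumerate(instance.groups):
        quality[d] = evaluate_quality_eur(
            g, instance.quality_functions[g.id], int(nl[d]), cfg.euros_per_qaly)
        minutes = tt[np.arange(instance.n_zips), assign[:, d]]
        travel[d] = (cfg.round_trip_factor * cfg.euros_per_travel_hour * g.n_visits
                     * float(np.sum(instance.demand[:, d] * minutes)) / 60.0)
    return float(np.sum(quality - travel)), quality, travel


def _minima_active(instance: Instance) -> bool:
    return any(instance.config.min_utilization(f) > 0 for f in FacilityType)


def _pair_travel_cost(instance: Instance) -> np.ndarray:
    """Euro cost of assigning pair (d, p) to site q, shape (nG*nZ, nS)."""
    cfg = instance.config
    rows = []
    for d, g in enumerate(instance.groups):
        coef = cfg.round_trip_factor * cfg.euros_per_travel_hour * g.n_visits / 60.0
        rows.append(coef * instance.demand[:, d][:, None] * instance.travel.minutes)
    return np.vstack(rows)


def _travel_totals(instance: Instance, combos: np.ndarray) -> np.ndarray:
    C = _pair_travel_cost(instance)
    L = C.shape[0]
    return C[np.arange(L)[None, :], combos].sum(axis=1)


def _quality_total(instance: Instance, offers: np.ndarray) -> float:
    cfg = instance.config
    nl = offers.sum(axis=0)
    return float(sum(
        evaluate_quality_eur(g, instance.quality_functions[g.id], int(nl[d]),
                             cfg.euros_per_qaly)
        for d, g in enumerate(instance.groups)))


def _feasible_mask(instance: Instance, combos: np.ndarray,
                   open_sites: np.ndarray) -> np.ndarray:
    """Utilization feasibility of each assignment combo (rows ordered d-major,
    p-minor to match the enumeration)."""
    cfg = instance.config
    mode = cfg.utilization_mode
    n = combos.shape[0]
    ok = np.ones(n, dtype=bool)
    tol = 1e-9
    for f in FacilityType:
        minu = cfg.min_utilization(f)
        if minu <= 0:
            continue
        w = np.concatenate([
            instance.demand[:, d] * g.usage[f]
            for d, g in enumerate(instance.groups)
        ])  # (nG*nZ,)
        for q in range(instance.n_sites):
            usage_q = ((combos == q) * w[None, :]).sum(axis=1)
            if mode is UtilizationMode.LITERAL:
                if open_sites[q]:
                    ok &= usage_q >= minu * (1 - 1e-9) - tol
            else:
                ok &= ~((usage_q > tol) & (usage_q < minu * (1 - 1e-9) - tol))
    return ok


def enumerate_optimum(
    instance: Instance, limits: Optional[OracleLimits] = None
) -> Solution:
    """Exhaustive optimum of the allocation problem.

    Enumerates all offering patterns Z consistent with co-location and travel
    coverage; open sites are exactly those with at least one offering (an open
    site without offerings never helps and, under the literal utilization
    mode, is infeasible).  Without utilization minima the optimal assignment
    given Z is the closed-form nearest-feasible map; with minima active the
    assignments are enumerated too.  Ties in the objective break toward the
    lexicographically smallest (Z, Y) encoding, so the result is deterministic.
    """
    limits = limits or OracleLimits()
    nZ, nS, nG = instance.n_zips, instance.n_sites, instance.n_groups
    if nZ > limits.max_zips or nS > limits.max_sites or nG > limits.max_groups:
        raise OracleSizeError(
            f"instance ({nZ} zips, {nS} sites, {nG} groups) exceeds oracle limits "
            f"({limits.max_zips}, {limits.max_sites}, {limits.max_groups})")

    tt = instance.travel.minutes
    minima = _minima_active(instance)

    # groups tied by co-location share one subset choice
    tied: Dict[int, int] = {}
    for g1, g2 in instance.colocate_pairs:
        tied[instance.group_index(g2)] = instance.group_index(g1)
    free_groups = [d for d in range(nG) if d not in tied]

    subsets = [np.array(s, dtype=np.int64)
               for r in range(1, nS + 1)
               for s in itertools.combinations(range(nS), r)]

    # coverage pre-filter per group: subset must reach every zip
    admissible: List[List[np.ndarray]] = []
    for d, g in enumerate(instance.groups):
        ok_mat = tt <= g.max_travel_min + 1e-9
        admissible.append([s for s in subsets if np.all(ok_mat[:, s].any(axis=1))])

    n_z_combos = 1
    for d in free_groups:
        n_z_combos *= len(admissible[d])
        if n_z_combos > limits.max_states:
            raise OracleSizeError(
                f"more than {limits.max_states} offering patterns to enumerate")

    best_obj = -math.inf
    best_key: Optional[tuple] = None
    best: Optional[Tuple[np.ndarray, np.ndarray]] = None

    def consider(offers: np.ndarray, assign: np.ndarray) -> None:
        nonlocal best_obj, best_key, best
        obj, _, _ = _objective(instance, offers, assign)
        key = (tuple(offers.ravel()), tuple(assign.ravel()))
        if obj > best_obj + 1e-12 or (abs(obj - best_obj) <= 1e-12
                                      and (best_key is None or key < best_key)):
            best_obj, best_key = obj, key
            best = (offers.copy(), assign.copy())

    for combo in itertools.product(*(admissible[d] for d in free_groups)):
        offers = np.zeros((nS, nG), dtype=np.int8)
        for d, s in zip(free_groups, combo):
            offers[s, d] = 1
        feasible = True
        for d2, d1 in tied.items():
            offers[:, d2] = offers[:, d1]
            # tied group must also satisfy its own coverage
            g2 = instance.groups[d2]
            s2 = np.nonzero(offers[:, d2])[0]
            ok = tt[:, s2] <= g2.max_travel_min + 1e-9
            if not np.all(ok.any(axis=1)):
                feasible = False
                break
        if not feasible:
            continue
        open_sites = (offers.sum(axis=1) > 0).astype(np.int8)

        if not minima:
            assign = nearest_feasible_assignment(instance, offers)
            consider(offers, assign)
            continue

        # enumerate assignments over admissible offering sites per (d, p),
        # vectorized over all combinations
        choice_sets: List[np.ndarray] = []
        n_states = 1
        for d, g in enumerate(instance.groups):
            s = np.nonzero(offers[:, d])[0]
            for p in range(nZ):
                ok = s[tt[p, s] <= g.max_travel_min + 1e-9]
                choice_sets.append(ok)
                n_states *= len(ok)
                if n_states > limits.max_states:
                    raise OracleSizeError(
                        f"assignment enumeration exceeds {limits.max_states} states "
                        f"(estimate {n_states}+)")
        combos = np.array(list(itertools.product(*choice_sets)), dtype=np.int64)
        feas = _feasible_mask(instance, combos, open_sites)
        if not feas.any():
            continue
        # itertools.product yields assignments in ascending lexicographic
        # order, so the first best index is the deterministic tie-break
        trav = _travel_totals(instance, combos)
        obj = _quality_total(instance, offers) - trav
        obj[~feas] = -math.inf
        best_i = int(np.argmax(obj))
        cand = np.nonzero(obj >= obj[best_i] - 1e-12)[0]
        best_i = int(cand[0])
        consider(offers, combos[best_i].reshape(nG, nZ).T)

    if best is None:
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
            diagnostics={"oracle": "no feasible candidate"},
        )

    offers, assign = best
    open_sites = (offers.sum(axis=1) > 0).astype(np.int8)
    obj, quality, travel = _objective(instance, offers, assign)
    return Solution(
        open_sites=open_sites,
        offers=offers,
        assign=assign,
        n_locations=offers.sum(axis=0).astype(np.int64),
        quality_eur=quality,
        travel_eur=travel,
        objective_eur=obj,
        solver_status=SolverStatus.OPTIMAL,
        gap=0.0,
    )
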