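"""Core data model for the hospital-landscape allocation problem.

The problem allocates diagnosis groups (disease clusters with a national annual
caseload) over candidate hospital sites.  Concentrating a group on few sites
raises quality per patient through the volume-outcome relationship, valued in
QALYs and monetized at a euro-per-QALY rate; it also raises travel cost for
patients, monetized per hour.  Hard constraints cap travel time per group and
require opened clinical facilities (operating rooms, wards, intensive-care
units) to reach a minimum annual utilization.

This module holds every symbol of the optimization model as a validated type,
plus :func:`validate_solution`, a feasibility certifier that is deliberately
independent of any solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Tuple

import numpy as np

__all__ = [
    "FacilityType",
    "Facility",
    "default_facilities",
    "CareClass",
    "VOCategory",
    "DiagnosisGroup",
    "ZipArea",
    "CandidateSite",
    "TravelTimeMatrix",
    "QualitySegment",
    "QualityFunction",
    "UtilizationMode",
    "ModelConfig",
    "Instance",
    "SolverStatus",
    "Solution",
    "Violation",
    "ValidationReport",
    "DimensionMismatchError",
    "validate_solution",
]


class FacilityType(str, Enum):
    """The three clinical facility kinds subject to minimum-utilization rules."""

    OR = "OR"      # operating rooms, utilization in hours/year
    WARD = "WARD"  # nursing ward, utilization in occupied-bed-days/year
    ICU = "ICU"    # intensive care, utilization in occupied-bed-days/year


@dataclass(frozen=True)
class Facility:
    """A facility kind together with its minimum efficient annual utilization.

    Units: OR in hours/year; WARD and ICU in occupied-bed-days/year.
    """

    id: FacilityType
    min_utilization: float

    def __post_init__(self) -> None:
        if self.min_utilization < 0:
            raise ValueError(f"min_utilization must be >= 0, got {self.min_utilization}")


#: Default minimum utilizations, from benchmark operating parameters:
#: OR: 65% of 48 weeks x 5 days x 8 hours; ICU: 6 beds occupied 365 days;
#: ward: 80% occupancy of 12 beds over 365 days.
DEFAULT_MIN_UTILIZATION: Dict[FacilityType, float] = {
    FacilityType.OR: 0.65 * 48 * 5 * 8,     # 1248 hours/year
    FacilityType.WARD: 0.80 * 12 * 365,     # 3504 bed-days/year
    FacilityType.ICU: 6 * 365,              # 2190 bed-days/year
}


def default_facilities() -> Tuple[Facility, ...]:
    """The three facilities with their default minimum utilizations."""
    return tuple(Facility(f, DEFAULT_MIN_UTILIZATION[f]) for f in FacilityType)


class CareClass(str, Enum):
    ACUTE = "acute"
    CHRONIC = "chronic"
    ELECTIVE = "elective"
    MIXED = "mixed"


class VOCategory(str, Enum):
    """Strength of a group's volume-outcome relationship relative to the
    reference group (breast-cancer-dominated neoplasms)."""

    HIGH = "high"
    INTERMEDIATE = "intermediate"
    LOW = "low"
    NONE = "none"


@dataclass(frozen=True)
class DiagnosisGroup:
    """One diagnosis group with its demand and resource profile.

    ``n_patients`` is the national annual admission count; ``n_visits`` the
    average number of trips per patient (treatment plus follow-up, all at the
    assigned location); ``max_travel_min`` the maximum acceptable one-way drive
    time; ``usage`` the per-patient facility consumption (OR hours, ward and
    ICU bed-days).  ``annual_cost_meur`` is descriptive metadata only.
    """

    id: int
    name: str
    care_class: CareClass
    vo_category: VOCategory
    n_patients: int
    n_visits: float
    max_travel_min: float
    usage: Mapping[FacilityType, float]
    annual_cost_meur: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError(f"group {self.id}: n_patients must be positive")
        if self.max_travel_min <= 0:
            raise ValueError(f"group {self.id}: max_travel_min must be positive")
        if self.n_visits <= 0:
            raise ValueError(f"group {self.id}: n_visits must be positive")
        missing = [f for f in FacilityType if f not in self.usage]
        if missing:
            raise ValueError(f"group {self.id}: usage missing entries for {missing}")
        if any(v < 0 for v in self.usage.values()):
            raise ValueError(f"group {self.id}: usage values must be >= 0")


@dataclass(frozen=True)
class ZipArea:
    """A demand zone: an aggregated zip-code area with its population and a
    planar coordinate (km)."""

    id: str
    population: float
    coords: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError(f"zip {self.id}: population must be positive")


@dataclass(frozen=True)
class CandidateSite:
    """A candidate hospital location."""

    id: str
    coords: Tuple[float, float]
    from_existing_hospital: bool = False


@dataclass(frozen=True)
class TravelTimeMatrix:
    """Dense one-way drive times in minutes, indexed (zip, site)."""

    minutes: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.minutes, dtype=float)
        object.__setattr__(self, "minutes", m)
        if m.ndim != 2:
            raise ValueError("travel-time matrix must be 2-D (zips x sites)")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("travel times must be finite and >= 0")


@dataclass(frozen=True)
class QualitySegment:
    """One linear piece ``a*NL + b`` of a per-patient quality function, valid
    for location counts in the closed interval [nl_lo, nl_hi].

    Adjacent segments share their boundary knot; continuity there makes the
    shared point unambiguous.
    """

    nl_lo: int
    nl_hi: int
    slope: float     # QALY/patient per additional location (<= 0 when a V-O relation exists)
    intercept: float  # QALY/patient

    def __post_init__(self) -> None:
        if self.nl_lo < 1 or self.nl_hi < self.nl_lo:
            raise ValueError(f"invalid segment interval [{self.nl_lo}, {self.nl_hi}]")

    def value(self, nl: float) -> float:
        return self.slope * nl + self.intercept

    def contains(self, nl: int) -> bool:
        return self.nl_lo <= nl <= self.nl_hi


KNOT_CONTINUITY_TOL = 1e-9  # QALY/patient


@dataclass(frozen=True)
class QualityFunction:
    """Piecewise-linear per-patient quality (QALY) versus location count."""

    group_id: int
    segments: Tuple[QualitySegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("quality function needs at least one segment")
        for s0, s1 in zip(segs, segs[1:]):
            if s1.nl_lo != s0.nl_hi:
                raise ValueError(
                    f"group {self.group_id}: segments must share knots; "
                    f"got [{s0.nl_lo},{s0.nl_hi}] then [{s1.nl_lo},{s1.nl_hi}]"
                )
            if abs(s0.value(s0.nl_hi) - s1.value(s0.nl_hi)) > KNOT_CONTINUITY_TOL:
                raise ValueError(
                    f"group {self.group_id}: discontinuity at knot {s0.nl_hi}"
                )

    @property
    def nl_min(self) -> int:
        return self.segments[0].nl_lo

    @property
    def nl_max(self) -> int:
        return self.segments[-1].nl_hi

    def segment_for(self, nl: int) -> QualitySegment:
        """The first segment whose interval contains ``nl``."""
        for seg in self.segments:
            if seg.contains(nl):
                return seg
        raise ValueError(
            f"group {self.group_id}: NL={nl} outside domain "
            f"[{self.nl_min}, {self.nl_max}]"
        )

    def segment_index_for(self, nl: int) -> int:
        for i, seg in enumerate(self.segments):
            if seg.contains(nl):
                return i
        raise ValueError(
            f"group {self.group_id}: NL={nl} outside domain "
            f"[{self.nl_min}, {self.nl_max}]"
        )

    def evaluate(self, nl: int) -> float:
        """Per-patient quality in QALYs at ``nl`` locations."""
        return self.segment_for(nl).value(nl)


class UtilizationMode(str, Enum):
    """How minimum facility utilization is enforced at open sites.

    ``conditional``: a facility at a site is either absent (zero usage) or
    efficiently used (usage >= minimum) — sites without, say, an OR simply do
    not operate one.  ``literal``: every open site must meet the minimum for
    every facility kind, which forces full-service hospitals everywhere.
    """

    CONDITIONAL = "conditional"
    LITERAL = "literal"


@dataclass(frozen=True)
class ModelConfig:
    """Economic and solver parameters of the allocation model.

    ``euros_per_qaly`` (EQ) monetizes quality; ``euros_per_travel_hour`` (ET)
    monetizes travel.  The default ET of 172 €/h combines taxi cost
    (2.20 €/km at 60 km/h, carrying patient plus companion) with two persons'
    lost income (32,000 € over 1,600 working hours each).
    """

    euros_per_qaly: float = 50_000.0
    euros_per_travel_hour: float = 172.0
    round_trip_factor: float = 2.0
    big_m: float = 1e6
    mip_gap: float = 1e-6
    utilization_mode: UtilizationMode = UtilizationMode.CONDITIONAL
    facilities: Tuple[Facility, ...] = field(default_factory=default_facilities)
    seed: int = 0
    max_refinement_iters: int = 10

    def __post_init__(self) -> None:
        if self.euros_per_qaly <= 0:
            raise ValueError("euros_per_qaly must be positive")
        if self.euros_per_travel_hour <= 0:
            raise ValueError("euros_per_travel_hour must be positive")
        if self.round_trip_factor <= 0 or self.big_m <= 0:
            raise ValueError("round_trip_factor and big_m must be positive")
        if self.mip_gap < 0:
            raise ValueError("mip_gap must be >= 0")
        if self.max_refinement_iters < 1:
            raise ValueError("max_refinement_iters must be >= 1")
        object.__setattr__(self, "utilization_mode", UtilizationMode(self.utilization_mode))
        if len({f.id for f in self.facilities}) != len(self.facilities):
            raise ValueError("duplicate facility kinds in config")

    def min_utilization(self, f: FacilityType) -> float:
        for fac in self.facilities:
            if fac.id == f:
                return fac.min_utilization
        return 0.0


#: Tolerance (patients) on per-group demand conservation after integer spreading.
DEMAND_CONSERVATION_TOL = 1.0


@dataclass
class Instance:
    """A complete allocation problem: demand geography, candidate sites, drive
    times, diagnosis groups with quality functions, and economic config."""

    groups: List[DiagnosisGroup]
    zips: List[ZipArea]
    sites: List[CandidateSite]
    travel: TravelTimeMatrix
    demand: np.ndarray  # (n_zips, n_groups) patients/year
    quality_functions: Dict[int, QualityFunction]
    colocate_pairs: List[Tuple[int, int]] = field(default_factory=lambda: [(21, 23)])
    config: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        self.demand = np.asarray(self.demand, dtype=float)
        self.validate()

    # -- index helpers -----------------------------------------------------
    @property
    def n_zips(self) -> int:
        return len(self.zips)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_index(self, group_id: int) -> int:
        for i, g in enumerate(self.groups):
            if g.id == group_id:
                return i
        raise KeyError(f"no group with id {group_id}")

    def validate(self) -> None:
        if len({s.id for s in self.sites}) != self.n_sites:
            raise ValueError("candidate site ids must be unique")
        if len({z.id for z in self.zips}) != self.n_zips:
            raise ValueError("zip ids must be unique")
        if len({g.id for g in self.groups}) != self.n_groups:
            raise ValueError("group ids must be unique")
        if self.travel.minutes.shape != (self.n_zips, self.n_sites):
            raise ValueError(
                f"travel matrix shape {self.travel.minutes.shape} != "
                f"({self.n_zips}, {self.n_sites})"
            )
        if self.demand.shape != (self.n_zips, self.n_groups):
            raise ValueError(
                f"demand shape {self.demand.shape} != ({self.n_zips}, {self.n_groups})"
            )
        if np.any(self.demand < 0):
            raise ValueError("demand entries must be >= 0")
        col = self.demand.sum(axis=0)
        for d, g in enumerate(self.groups):
            if abs(col[d] - g.n_patients) > DEMAND_CONSERVATION_TOL:
                raise ValueError(
                    f"group {g.id}: zip demand sums to {col[d]}, "
                    f"expected {g.n_patients} (tolerance {DEMAND_CONSERVATION_TOL})"
                )
        gids = {g.id for g in self.groups}
        for g1, g2 in self.colocate_pairs:
            if g1 not in gids or g2 not in gids:
                raise ValueError(f"colocation pair ({g1}, {g2}) references unknown group")
        for g in self.groups:
            if g.id not in self.quality_functions:
                raise ValueError(f"group {g.id} lacks a quality function")
            qf = self.quality_functions[g.id]
            if qf.nl_min > 1 or qf.nl_max < self.n_sites:
                raise ValueError(
                    f"group {g.id}: quality function domain [{qf.nl_min}, {qf.nl_max}] "
                    f"must cover [1, {self.n_sites}]"
                )

    def equals(self, other: "Instance", rtol: float = 1e-9, atol: float = 1e-9) -> bool:
        """Structural equality with numeric tolerance (for round-trip tests)."""
        if (self.groups != other.groups or self.zips != other.zips
                or self.sites != other.sites
                or self.colocate_pairs != other.colocate_pairs
                or self.config != other.config
                or self.quality_functions != other.quality_functions):
            return False
        return (np.allclose(self.travel.minutes, other.travel.minutes, rtol=rtol, atol=atol)
                and np.allclose(self.demand, other.demand, rtol=rtol, atol=atol))


class SolverStatus(str, Enum):
    OPTIMAL = "optimal"
    FEASIBLE = "feasible"
    INFEASIBLE = "infeasible"
    ERROR = "error"


@dataclass
class Solution:
    """An allocation: open sites X, group offerings Z, zip assignments Y, and
    the derived per-group location counts and euro-valued objective terms.

    ``assign[p, d]`` stores the index of the site serving zip ``p`` for group
    ``d`` (-1 when unassigned), which encodes the binary Y with single
    assignment built in.
    """

    open_sites: np.ndarray      # (n_sites,) 0/1
    offers: np.ndarray          # (n_sites, n_groups) 0/1
    assign: np.ndarray          # (n_zips, n_groups) site index or -1
    n_locations: np.ndarray     # (n_groups,) int
    quality_eur: np.ndarray     # (n_groups,)
    travel_eur: np.ndarray      # (n_groups,)
    objective_eur: float
    solver_status: SolverStatus = SolverStatus.OPTIMAL
    gap: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.open_sites = np.asarray(self.open_sites, dtype=np.int8)
        self.offers = np.asarray(self.offers, dtype=np.int8)
        self.assign = np.asarray(self.assign, dtype=np.int64)
        self.n_locations = np.asarray(self.n_locations, dtype=np.int64)
        self.quality_eur = np.asarray(self.quality_eur, dtype=float)
        self.travel_eur = np.asarray(self.travel_eur, dtype=float)
        self.solver_status = SolverStatus(self.solver_status)


@dataclass(frozen=True)
class Violation:
    """One named constraint violation found by the validator."""

    kind: str
    where: tuple
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind}{self.where}: {self.detail}"


ValidationReport = List[Violation]


class DimensionMismatchError(ValueError):
    """Solution index sets do not match the instance (a structural error,
    distinct from infeasibility)."""


_UTIL_REL_TOL = 1e-6
_TRAVEL_TOL_MIN = 1e-9
_OBJECTIVE_REL_TOL = 1e-6


def _site_usage(instance: Instance, assign: np.ndarray) -> Dict[FacilityType, np.ndarray]:
    """Annual facility usage per site implied by an assignment: for each
    facility f and site q, sum of demand[p,d] * U[f,d] over pairs assigned to q."""
    nS = instance.n_sites
    out: Dict[FacilityType, np.ndarray] = {}
    for f in FacilityType:
        u = np.array([g.usage[f] for g in instance.groups])  # (n_groups,)
        acc = np.zeros(nS)
        for d in range(instance.n_groups):
            if u[d] == 0:
                continue
            a = assign[:, d]
            mask = a >= 0
            np.add.at(acc, a[mask], instance.demand[mask, d] * u[d])
        out[f] = acc
    return out


def validate_solution(instance: Instance, sol: Solution) -> ValidationReport:
    """Certify feasibility of ``sol`` against ``instance``, independent of any
    solver.  Returns all violations found; an empty report means feasible.

    Checks: (a) every zip-group pair is assigned to exactly one site;
    (b) assignments only to offering sites; (c) offerings only at open sites;
    (d) assigned travel within the group's maximum; (e) minimum facility
    utilization per the configured mode; (f) co-located pairs offered at
    identical site sets; (g) location-count accounting NL_d = sum_q Z_{q,d};
    plus objective bookkeeping against the stored per-group euro terms.
    """
    nZ, nS, nG = instance.n_zips, instance.n_sites, instance.n_groups
    if sol.open_sites.shape != (nS,):
        raise DimensionMismatchError(
            f"open_sites has shape {sol.open_sites.shape}, expected ({nS},)")
    if sol.offers.shape != (nS, nG):
        raise DimensionMismatchError(
            f"offers has shape {sol.offers.shape}, expected ({nS}, {nG})")
    if sol.assign.shape != (nZ, nG):
        raise DimensionMismatchError(
            f"assign has shape {sol.assign.shape}, expected ({nZ}, {nG})")
    if sol.n_locations.shape != (nG,):
        raise DimensionMismatchError(
            f"n_locations has shape {sol.n_locations.shape}, expected ({nG},)")
    if np.any(sol.assign >= nS):
        raise DimensionMismatchError("assign references site index out of range")

    report: ValidationReport = []
    tt = instance.travel.minutes

    # (a) completeness
    for p in range(nZ):
        for d in range(nG):
            if sol.assign[p, d] < 0:
                report.append(Violation(
                    "assignment_incomplete", (instance.zips[p].id, instance.groups[d].id),
                    "no site assigned"))

    # (b) Y <= Z, (d) travel limit
    for d, g in enumerate(instance.groups):
        a = sol.assign[:, d]
        for p in range(nZ):
            q = a[p]
            if q < 0:
                continue
            if not sol.offers[q, d]:
                report.append(Violation(
                    "linking_offer", (instance.zips[p].id, instance.sites[q].id, g.id),
                    "assigned to a site not offering the group"))
            t = tt[p, q]
            if t > g.max_travel_min + _TRAVEL_TOL_MIN:
                report.append(Violation(
                    "max_travel", (instance.zips[p].id, instance.sites[q].id, g.id),
                    f"travel {t:.1f} min exceeds limit {g.max_travel_min:.1f}"))

    # (c) Z <= X
    for q in range(nS):
        for d in range(nG):
            if sol.offers[q, d] and not sol.open_sites[q]:
                report.append(Violation(
                    "linking_open", (instance.sites[q].id, instance.groups[d].id),
                    "offering at a closed site"))

    # (e) minimum utilization
    usage = _site_usage(instance, sol.assign)
    mode = instance.config.utilization_mode
    for f in FacilityType:
        minu = instance.config.min_utilization(f)
        if minu <= 0:
            continue
        tol = _UTIL_REL_TOL * minu
        for q in range(nS):
            u = usage[f][q]
            if mode is UtilizationMode.LITERAL:
                bad = sol.open_sites[q] and u < minu - tol
            else:
                bad = 0 < u < minu - tol
            if bad:
                report.append(Violation(
                    "min_utilization", (instance.sites[q].id, f.value),
                    f"usage {u:.1f} below minimum {minu:.1f}"))

    # (f) co-location
    for g1, g2 in instance.colocate_pairs:
        d1, d2 = instance.group_index(g1), instance.group_index(g2)
        diff = np.nonzero(sol.offers[:, d1] != sol.offers[:, d2])[0]
        for q in diff:
            report.append(Violation(
                "colocation", (instance.sites[q].id, g1, g2),
                "co-located groups offered at different site sets"))

    # (g) NL accounting
    nl = sol.offers.sum(axis=0)
    for d in range(nG):
        if sol.n_locations[d] != nl[d]:
            report.append(Violation(
                "nl_accounting", (instance.groups[d].id,),
                f"stored NL={sol.n_locations[d]} but offers sum to {nl[d]}"))

    # objective bookkeeping
    total = float(np.sum(sol.quality_eur - sol.travel_eur))
    scale = max(1.0, abs(total), abs(sol.objective_eur))
    if abs(sol.objective_eur - total) > _OBJECTIVE_REL_TOL * scale:
        report.append(Violation(
            "objective_mismatch", (),
            f"objective {sol.objective_eur} != sum of components {total}"))

    return report
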