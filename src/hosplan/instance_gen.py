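"""Synthetic-instance generation and the packaged diagnosis-group table.

The real planning inputs — zip-level demographics, the national drive-time
matrix and registry resource-use data — are proprietary, so this module
emulates their statistical shape: clustered zip populations, road-network-like
travel times, demand spread proportional to population, and care-class-typed
per-patient resource usage.  The diagnosis-group table itself (admissions,
volume-outcome category, travel limits) is shipped verbatim as package data.

The generator's scales default to the national setting (794 zip areas, 150
candidate sites of which 88 at existing hospital locations) and scale down
cleanly for desk-size experiments.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .calibration import CalibrationSpec, build_quality_functions
from .domain import (
    CandidateSite,
    CareClass,
    DiagnosisGroup,
    FacilityType,
    Instance,
    ModelConfig,
    TravelTimeMatrix,
    VOCategory,
    ZipArea,
)

__all__ = [
    "GeneratorConfig",
    "scaled_extent_km",
    "DEFAULT_VISITS_PER_PATIENT",
    "load_table2_fixture",
    "generate_zips",
    "select_candidate_sites",
    "build_travel_matrix",
    "spread_demand",
    "generate_usage",
    "make_instance",
    "make_micro_instance",
]


#: Average trips per patient (treatment plus follow-up) by care class.  Chronic
#: care requires frequent visits; acute episodes few.
DEFAULT_VISITS_PER_PATIENT: Dict[CareClass, float] = {
    CareClass.CHRONIC: 8.0,
    CareClass.ELECTIVE: 3.0,
    CareClass.ACUTE: 2.0,
    CareClass.MIXED: 5.0,
}

#: Per-patient facility-usage sampling ranges by care class:
#: (OR hours, ward bed-days, ICU bed-days), each a (low, high) uniform range.
#: Chronic care is outpatient-heavy: no surgery, no intensive care.
USAGE_RANGES: Dict[CareClass, Dict[FacilityType, Tuple[float, float]]] = {
    CareClass.CHRONIC: {
        FacilityType.OR: (0.0, 0.0),
        FacilityType.WARD: (3.0, 8.0),
        FacilityType.ICU: (0.0, 0.0),
    },
    CareClass.ELECTIVE: {
        FacilityType.OR: (1.0, 3.0),
        FacilityType.WARD: (1.0, 4.0),
        FacilityType.ICU: (0.01, 0.10),
    },
    CareClass.ACUTE: {
        FacilityType.OR: (0.5, 2.0),
        FacilityType.WARD: (2.0, 7.0),
        FacilityType.ICU: (0.05, 0.30),
    },
    CareClass.MIXED: {
        FacilityType.OR: (0.8, 2.5),
        FacilityType.WARD: (2.0, 6.0),
        FacilityType.ICU: (0.02, 0.15),
    },
}


#: Area served per candidate site in the national configuration
#: (~200 km x 200 km country, 150 candidate sites divided into ~440 km² cells).
KM2_PER_SITE = 200.0 * 200.0 / 150.0


def scaled_extent_km(n_sites: int) -> float:
    """Region side length that keeps the national site density when an
    instance is scaled down: sqrt(n_sites x the national km² per site).
    Scaled-down instances should preserve density, not extent, so that
    accessibility statistics stay comparable."""
    return math.sqrt(n_sites * KM2_PER_SITE)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic geography and demand process.

    The region is a square of side ``region_extent_km`` (default 200 km, a
    Netherlands-sized country).  Zip locations mix a few urban cores with a
    uniform background; populations are lognormal and rescaled to
    ``total_population``.  Travel times are detoured Euclidean distances at
    ``speed_kmh`` plus truncated Gaussian noise.
    """

    n_zips: int = 794
    n_sites: int = 150
    n_sites_from_population_centers: int = 88
    region_extent_km: float = 200.0
    n_urban_cores: int = 5
    urban_fraction: float = 0.75
    urban_sd_km: float = 12.0
    population_lognormal_mu: float = 9.5
    population_lognormal_sigma: float = 1.0
    total_population: float = 16_500_000.0
    road_factor: float = 1.3
    speed_kmh: float = 60.0
    travel_noise_sd_min: float = 1.5
    coverage_minutes: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_zips < 1:
            raise ValueError("n_zips must be >= 1")
        if not (self.n_sites_from_population_centers <= self.n_sites <= self.n_zips):
            raise ValueError(
                "need n_sites_from_population_centers <= n_sites <= n_zips")
        if self.region_extent_km <= 0 or self.speed_kmh <= 0:
            raise ValueError("region_extent_km and speed_kmh must be positive")
        if self.road_factor < 1.0:
            raise ValueError("road_factor must be >= 1")
        if self.travel_noise_sd_min < 0:
            raise ValueError("travel_noise_sd_min must be >= 0")


# ---------------------------------------------------------------------------
# Packaged diagnosis-group table
# ---------------------------------------------------------------------------

def load_table2_fixture(
    include_excluded: bool = False,
    visits: Optional[Dict[CareClass, float]] = None,
) -> List[DiagnosisGroup]:
    """Load the packaged 30-group diagnosis table.

    One printed row ("Signs, symptoms and ill-defined conditions") was dropped
    from the model set for lack of information; pass ``include_excluded=True``
    to get it too (with id 0).  Per-patient facility usage is initialised to
    zero — use :func:`generate_usage` to sample registry-like values.
    """
    visits = visits or DEFAULT_VISITS_PER_PATIENT
    groups: List[DiagnosisGroup] = []
    ref = resources.files("hosplan").joinpath("data/diagnosis_groups.csv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            included = row["included"] == "1"
            if not included and not include_excluded:
                continue
            care = CareClass(row["care_class"])
            groups.append(DiagnosisGroup(
                id=int(row["model_id"]) if row["model_id"] else 0,
                name=row["name"],
                care_class=care,
                vo_category=VOCategory(row["vo_category"]),
                n_patients=int(row["n_admissions"]),
                n_visits=visits[care],
                max_travel_min=float(row["max_travel_min"]),
                usage={f: 0.0 for f in FacilityType},
                annual_cost_meur=float(row["annual_cost_meur"]),
            ))
    return groups


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def generate_zips(cfg: GeneratorConfig) -> List[ZipArea]:
    """Zip areas from a clustered spatial process.

    A few urban cores attract ``urban_fraction`` of the zips (Gaussian scatter
    around each core); the rest fall uniformly over the square region.
    Populations are i.i.d. lognormal, then rescaled so they sum exactly to
    ``total_population``.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.region_extent_km
    cores = rng.uniform(0.15 * L, 0.85 * L, size=(cfg.n_urban_cores, 2))
    coords = np.empty((cfg.n_zips, 2))
    is_urban = rng.random(cfg.n_zips) < cfg.urban_fraction
    core_of = rng.integers(0, cfg.n_urban_cores, size=cfg.n_zips)
    for i in range(cfg.n_zips):
        if is_urban[i]:
            pt = cores[core_of[i]] + rng.normal(0.0, cfg.urban_sd_km, size=2)
            coords[i] = np.clip(pt, 0.0, L)
        else:
            coords[i] = rng.uniform(0.0, L, size=2)
    pops = rng.lognormal(cfg.population_lognormal_mu,
                         cfg.population_lognormal_sigma, size=cfg.n_zips)
    pops *= cfg.total_population / pops.sum()
    return [
        ZipArea(id=f"z{i:04d}", population=float(pops[i]),
                coords=(float(coords[i, 0]), float(coords[i, 1])))
        for i in range(cfg.n_zips)
    ]


def _weighted_pmedian_cost(zx: np.ndarray, w: np.ndarray, centers: np.ndarray) -> float:
    d = np.linalg.norm(zx[:, None, :] - centers[None, :, :], axis=2)
    return float((w * d.min(axis=1)).sum())


def select_candidate_sites(
    zips: Sequence[ZipArea], cfg: GeneratorConfig
) -> List[CandidateSite]:
    """Place candidate hospital sites at zip locations.

    The first ``n_sites_from_population_centers`` sites sit at the
    highest-population zips (a proxy for existing hospitals).  The remaining
    sites are chosen to make total population-weighted driving distance small:
    greedy population-weighted p-median addition followed by single-swap local
    search.  Ties break lexicographically on zip index; deterministic.

    When ``cfg.coverage_minutes > 0`` the candidate network is additionally
    planned under the accessibility norm, as real hospital networks are:
    before the p-median fill, sites are added greedily by covered population
    until every zip lies within that drive time of some site (with a safety
    margin for travel-time noise), and the swap search only accepts swaps
    preserving coverage.  A warning is issued if the site budget cannot cover
    every zip.
    """
    n = len(zips)
    if cfg.n_sites > n:
        raise ValueError("n_sites exceeds number of zips")
    zx = np.array([z.coords for z in zips])
    w = np.array([z.population for z in zips])

    if len(np.unique(zx, axis=0)) < n:
        import warnings
        warnings.warn("coincident zip coordinates; duplicate sites removed")

    # stable ordering: population descending, index ascending
    order = sorted(range(n), key=lambda i: (-w[i], i))
    chosen: List[int] = []
    seen_coords = set()
    for i in order:
        if len(chosen) >= cfg.n_sites_from_population_centers:
            break
        key = (round(zx[i, 0], 9), round(zx[i, 1], 9))
        if key in seen_coords:
            continue
        chosen.append(i)
        seen_coords.add(key)
    n_fixed = len(chosen)

    dist = np.linalg.norm(zx[:, None, :] - zx[None, :, :], axis=2)  # zip x zip
    if chosen:
        best_d = dist[:, chosen].min(axis=1)
    else:
        best_d = np.full(n, np.inf)

    cover_km = math.inf
    if cfg.coverage_minutes > 0:
        # margin so truncated-Gaussian travel noise cannot break the norm
        margin = 5.0 * cfg.travel_noise_sd_min
        cover_km = max(cfg.coverage_minutes - margin, 1.0) \
            * cfg.speed_kmh / 60.0 / cfg.road_factor

    # phase 1 (only with a coverage norm): greedy max covered population
    if np.isfinite(cover_km):
        while len(chosen) < cfg.n_sites:
            uncovered = best_d > cover_km
            if not uncovered.any():
                break
            gain = (w[uncovered, None] * (dist[uncovered, :] <= cover_km)).sum(axis=0)
            gain[chosen] = -np.inf
            j = int(np.argmax(gain))
            chosen.append(j)
            best_d = np.minimum(best_d, dist[:, j])
        if (best_d > cover_km).any():
            import warnings
            warnings.warn(
                f"site budget {cfg.n_sites} cannot cover every zip within "
                f"{cfg.coverage_minutes:g} min")

    # phase 2: greedy p-median addition
    while len(chosen) < cfg.n_sites:
        improve = (w[:, None] * np.minimum(best_d[:, None], dist)).sum(axis=0)
        improve[chosen] = np.inf
        j = int(np.argmin(improve))
        chosen.append(j)
        best_d = np.minimum(best_d, dist[:, j])

    # phase 3: single-swap local search over the free (non-fixed) sites,
    # rejecting swaps that would break coverage
    improved = True
    while improved:
        improved = False
        chosen_set = set(chosen)
        current = (w * dist[:, chosen].min(axis=1)).sum()
        for pos in range(n_fixed, len(chosen)):
            others = chosen[:pos] + chosen[pos + 1:]
            base_d = dist[:, others].min(axis=1) if others else np.full(n, np.inf)
            cand_d = np.minimum(base_d[:, None], dist)
            cand_cost = (w[:, None] * cand_d).sum(axis=0)
            if np.isfinite(cover_km):
                cand_cost[(cand_d > cover_km).any(axis=0)] = np.inf
            for j in chosen_set:
                cand_cost[j] = np.inf
            j = int(np.argmin(cand_cost))
            if cand_cost[j] < current - 1e-9:
                chosen[pos] = j
                improved = True
                break

    chosen_sorted = sorted(set(chosen))
    return [
        CandidateSite(
            id=f"s{k:03d}",
            coords=zips[i].coords,
            from_existing_hospital=(i in chosen[:n_fixed]),
        )
        for k, i in enumerate(chosen_sorted)
    ]


def build_travel_matrix(
    zips: Sequence[ZipArea], sites: Sequence[CandidateSite], cfg: GeneratorConfig
) -> TravelTimeMatrix:
    """Drive times in minutes: detoured Euclidean distance at cruise speed plus
    truncated-at-zero Gaussian noise.  Co-located pairs get exactly zero before
    noise; noise is deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed + 1)
    zx = np.array([z.coords for z in zips])
    sx = np.array([s.coords for s in sites])
    km = np.linalg.norm(zx[:, None, :] - sx[None, :, :], axis=2)
    minutes = km * cfg.road_factor / cfg.speed_kmh * 60.0
    if cfg.travel_noise_sd_min > 0:
        noise = rng.normal(0.0, cfg.travel_noise_sd_min, size=minutes.shape)
        minutes = np.maximum(minutes + noise, 0.0)
        minutes[km == 0.0] = np.maximum(minutes[km == 0.0], 0.0)
    return TravelTimeMatrix(minutes=minutes)


def spread_demand(
    groups: Sequence[DiagnosisGroup], zips: Sequence[ZipArea]
) -> np.ndarray:
    """Spread each group's national caseload over zips proportionally to
    population, with largest-remainder rounding so every column sums exactly
    to the group's admission count."""
    pops = np.array([z.population for z in zips])
    shares = pops / pops.sum()
    out = np.zeros((len(zips), len(groups)))
    for d, g in enumerate(groups):
        raw = shares * g.n_patients
        base = np.floor(raw)
        remainder = int(round(g.n_patients - base.sum()))
        frac = raw - base
        # largest remainders first; ties broken by zip index for determinism
        order = np.lexsort((np.arange(len(zips)), -frac))
        base[order[:remainder]] += 1
        out[:, d] = base
    return out


def generate_usage(
    groups: Sequence[DiagnosisGroup], seed: int
) -> Dict[Tuple[FacilityType, int], float]:
    """Sample per-patient facility usage U_{f,d} from care-class-conditioned
    uniform ranges (see ``USAGE_RANGES``).  Deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    out: Dict[Tuple[FacilityType, int], float] = {}
    for g in groups:
        ranges = USAGE_RANGES[g.care_class]
        for f in FacilityType:
            lo, hi = ranges[f]
            out[(f, g.id)] = float(rng.uniform(lo, hi)) if hi > lo else lo
    return out


def _apply_usage(
    groups: Sequence[DiagnosisGroup], usage: Dict[Tuple[FacilityType, int], float]
) -> List[DiagnosisGroup]:
    return [
        replace(g, usage={f: usage[(f, g.id)] for f in FacilityType}) for g in groups
    ]


def make_instance(
    cfg: GeneratorConfig,
    groups: Optional[Sequence[DiagnosisGroup]] = None,
    config: Optional[ModelConfig] = None,
    calibration: Optional[CalibrationSpec] = None,
    convex_factor: float = 1.0,
) -> Instance:
    """Generate a complete synthetic instance.

    Uses the packaged diagnosis-group table by default, samples geography,
    travel times, demand and resource usage under ``cfg.seed``, and calibrates
    quality functions on [1, n_sites].
    """
    if groups is None:
        groups = load_table2_fixture()
    calibration = calibration or CalibrationSpec()
    config = config or ModelConfig(seed=cfg.seed)
    zips = generate_zips(cfg)
    sites = select_candidate_sites(zips, cfg)
    travel = build_travel_matrix(zips, sites, cfg)
    demand = spread_demand(groups, zips)
    groups = _apply_usage(groups, generate_usage(groups, cfg.seed + 2))
    qfs = build_quality_functions(groups, calibration, cfg.n_sites, convex_factor)
    gids = {g.id for g in groups}
    pairs = [(a, b) for a, b in [(21, 23)] if a in gids and b in gids]
    return Instance(
        groups=list(groups),
        zips=zips,
        sites=sites,
        travel=travel,
        demand=demand,
        quality_functions=qfs,
        colocate_pairs=pairs,
        config=config,
    )


# ---------------------------------------------------------------------------
# Micro instances for cross-validation against exhaustive enumeration
# ---------------------------------------------------------------------------

def make_micro_instance(
    seed: int,
    n_zips: int = 4,
    n_sites: int = 3,
    n_groups: int = 2,
    with_minima: bool = False,
    vo_categories: Optional[Sequence[VOCategory]] = None,
    colocate: bool = False,
    maxt_min: float = 240.0,
    n_patients_scale: int = 60,
    reference_gain_qaly: float = 0.5,
) -> Instance:
    """A small random instance solvable by exhaustive enumeration.

    When ``with_minima`` is set, per-facility minimum utilizations are drawn
    as a 5-35% share of the facility's total generated usage, so the minima
    bind without being trivially infeasible.  All randomness flows from
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    cfg = GeneratorConfig(
        n_zips=n_zips,
        n_sites=n_sites,
        n_sites_from_population_centers=min(2, n_sites),
        region_extent_km=100.0,
        n_urban_cores=2,
        total_population=float(n_zips) * 10_000.0,
        travel_noise_sd_min=1.0,
        coverage_minutes=0.0,  # micro maxt is generous; no repair needed
        seed=seed,
    )
    zips = generate_zips(cfg)
    sites = select_candidate_sites(zips, cfg)
    travel = build_travel_matrix(zips, sites, cfg)

    all_cats = list(VOCategory)
    all_classes = list(CareClass)
    cats = list(vo_categories) if vo_categories else [
        all_cats[int(rng.integers(len(all_cats)))] for _ in range(n_groups)
    ]
    classes = [all_classes[int(rng.integers(len(all_classes)))]
               for _ in range(n_groups)]
    groups = [
        DiagnosisGroup(
            id=d + 1,
            name=f"micro-{d + 1}",
            care_class=CareClass(classes[d]),
            vo_category=VOCategory(cats[d]),
            n_patients=int(rng.integers(n_patients_scale, 4 * n_patients_scale)),
            n_visits=DEFAULT_VISITS_PER_PATIENT[CareClass(classes[d])],
            max_travel_min=maxt_min,
            usage={f: 0.0 for f in FacilityType},
        )
        for d in range(n_groups)
    ]
    demand = spread_demand(groups, zips)
    groups = _apply_usage(groups, generate_usage(groups, seed + 2))

    from .domain import Facility  # local to keep the header tight

    if with_minima:
        total_usage = {
            f: sum(g.n_patients * g.usage[f] for g in groups) for f in FacilityType
        }
        facilities = tuple(
            Facility(f, float(rng.uniform(0.05, 0.35)) * total_usage[f])
            for f in FacilityType
        )
    else:
        facilities = tuple(Facility(f, 0.0) for f in FacilityType)

    # Steeper reference anchor at micro scale so quality and travel compete
    # inside [1, n_sites].
    calibration = CalibrationSpec(
        reference_gain_qaly=reference_gain_qaly,
        reference_nl_from=max(n_sites, 2),
        reference_nl_to=1,
        baseline_nl=max(n_sites, 2),
        segmentation=(1, max(n_sites, 2)),
    )
    config = ModelConfig(seed=seed, facilities=facilities)
    qfs = build_quality_functions(groups, calibration, n_sites)
    pairs = [(1, 2)] if (colocate and n_groups >= 2) else []
    return Instance(
        groups=groups,
        zips=zips,
        sites=sites,
        travel=travel,
        demand=demand,
        quality_functions=qfs,
        colocate_pairs=pairs,
        config=config,
    )
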