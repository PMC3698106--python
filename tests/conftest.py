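"""Shared builders: hand-sized instances with known geometry."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pytest

from hosplan.domain import (
    CandidateSite,
    CareClass,
    DiagnosisGroup,
    Facility,
    FacilityType,
    Instance,
    ModelConfig,
    QualityFunction,
    QualitySegment,
    TravelTimeMatrix,
    VOCategory,
    ZipArea,
)


def zero_usage():
    return {f: 0.0 for f in FacilityType}


def no_minima():
    return tuple(Facility(f, 0.0) for f in FacilityType)


def flat_quality(group_id: int, n_sites: int) -> QualityFunction:
    return QualityFunction(group_id, (QualitySegment(1, max(n_sites, 2), 0.0, 0.0),))


def line_instance(
    xs: Sequence[float] = (10.0, 30.0, 50.0, 70.0, 90.0),
    pops: Optional[Sequence[float]] = None,
    segments: Optional[Tuple[QualitySegment, ...]] = None,
    n_patients: int = 1000,
    n_visits: float = 1.0,
    max_travel_min: float = 1000.0,
    euros_per_travel_hour: float = 30.0,
    euros_per_qaly: float = 50_000.0,
) -> Instance:
    """Zips and co-located sites on a line; travel minutes equal |dx| km.

    With the defaults (5 equidistant zips, equal demand 200 each, ET=30 so a
    patient-minute costs 1 euro), the optimal k-site travel totals are
    24000, 12000, 8000, 4000, 0 euros for k = 1..5.
    """
    n = len(xs)
    pops = list(pops) if pops is not None else [100.0] * n
    zips = [ZipArea(f"z{i}", pops[i], (xs[i], 0.0)) for i in range(n)]
    sites = [CandidateSite(f"s{i}", (xs[i], 0.0)) for i in range(n)]
    tt = np.abs(np.subtract.outer(np.array(xs), np.array(xs)))
    group = DiagnosisGroup(
        id=1, name="line", care_class=CareClass.ELECTIVE,
        vo_category=VOCategory.HIGH, n_patients=n_patients, n_visits=n_visits,
        max_travel_min=max_travel_min, usage=zero_usage(),
    )
    share = np.array(pops) / sum(pops)
    demand = np.round(share * n_patients)[:, None]
    demand[0, 0] += n_patients - demand.sum()
    if segments is None:
        qf = flat_quality(1, n)
    else:
        qf = QualityFunction(1, segments)
    config = ModelConfig(
        euros_per_qaly=euros_per_qaly,
        euros_per_travel_hour=euros_per_travel_hour,
        facilities=no_minima(),
    )
    return Instance(
        groups=[group], zips=zips, sites=sites,
        travel=TravelTimeMatrix(tt), demand=demand,
        quality_functions={1: qf}, colocate_pairs=[], config=config,
    )


def tiny_instance(
    tt_min: float = 10.0,
    maxt: float = 45.0,
    minima: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    usage: Optional[dict] = None,
    mode: str = "conditional",
) -> Instance:
    """One zip, one site, one group — the smallest well-posed problem."""
    group = DiagnosisGroup(
        id=1, name="tiny", care_class=CareClass.ACUTE,
        vo_category=VOCategory.NONE, n_patients=10, n_visits=2.0,
        max_travel_min=maxt, usage=usage or zero_usage(),
    )
    facilities = tuple(
        Facility(f, m) for f, m in zip(FacilityType, minima)
    )
    return Instance(
        groups=[group],
        zips=[ZipArea("z0", 100.0, (0.0, 0.0))],
        sites=[CandidateSite("s0", (1.0, 0.0))],
        travel=TravelTimeMatrix(np.array([[tt_min]])),
        demand=np.array([[10.0]]),
        quality_functions={1: flat_quality(1, 1)},
        colocate_pairs=[],
        config=ModelConfig(facilities=facilities, utilization_mode=mode),
    )


# Two-segment quality functions on the 5-point line instance (EQ=50000,
# NP=1000): per-location quality steps of 13000/5000 euros on the low/high
# ranges, against travel savings of 12000, 4000, 4000, 4000 euros for the
# 1->2, 2->3, 3->4, 4->5 location steps.
SEGMENTS_FIXED_POINT = (
    QualitySegment(1, 3, -2.6e-4, 9.8e-4),   # steep below 3 locations
    QualitySegment(3, 5, -1.0e-4, 5.0e-4),   # shallow above
)
SEGMENTS_CYCLE = (
    QualitySegment(1, 3, -0.6e-4, 7.0e-4),   # shallow below 3 locations
    QualitySegment(3, 5, -2.6e-4, 1.3e-3),   # steep above
)
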