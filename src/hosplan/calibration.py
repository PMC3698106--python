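"""Volume-outcome calibration: turning category labels into quality functions.

Each diagnosis group carries a volume-outcome category (high / intermediate /
low / none).  The high category is anchored on the best-quantified case in the
literature, breast-cancer care inside the neoplasms group: concentrating that
care from 94 hospitals to 15 specialized centers gains on average 0.5 QALY per
patient.  That pins the reference slope at -0.5/79 QALY per patient per
additional location; the other categories scale it by fixed ratios
(intermediate 50%, low 5%, none 0%).

Per-patient quality is expressed as a gain versus the status quo: the default
build normalizes the intercept so that quality is zero at the baseline
location count (94).  Shifting by a constant never changes the optimal
allocation, and gains-versus-baseline make reports directly interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

from .domain import DiagnosisGroup, QualityFunction, QualitySegment, VOCategory

__all__ = [
    "CalibrationSpec",
    "DegenerateAnchorError",
    "OutOfDomainError",
    "calibrate_slopes",
    "build_quality_function",
    "build_quality_functions",
    "evaluate_quality_eur",
]


class DegenerateAnchorError(ValueError):
    """The concentration anchor has zero span (from == to locations)."""


class OutOfDomainError(ValueError):
    """A location count falls outside every segment of a quality function."""


def _default_ratios() -> Dict[VOCategory, float]:
    return {
        VOCategory.HIGH: 1.0,
        VOCategory.INTERMEDIATE: 0.5,
        VOCategory.LOW: 0.05,
        VOCategory.NONE: 0.0,
    }


@dataclass(frozen=True)
class CalibrationSpec:
    """Parameters of the volume-outcome calibration.

    ``reference_gain_qaly`` over the concentration ``reference_nl_from`` →
    ``reference_nl_to`` fixes the high-category slope; ``category_ratio``
    scales the remaining categories.  ``baseline_nl`` is the location count at
    which quality gain is defined as zero (the status quo).  ``segmentation``
    lists the knots used when a piecewise build is requested; they bracket the
    location-count range where optima are expected.
    """

    reference_gain_qaly: float = 0.5
    reference_nl_from: int = 94
    reference_nl_to: int = 15
    category_ratio: Mapping[VOCategory, float] = field(default_factory=_default_ratios)
    baseline_nl: int = 94
    segmentation: Tuple[int, ...] = (1, 15, 40, 94)

    def __post_init__(self) -> None:
        if self.reference_gain_qaly <= 0:
            raise ValueError("reference_gain_qaly must be positive")
        if self.reference_nl_from == self.reference_nl_to:
            raise DegenerateAnchorError(
                "reference_nl_from and reference_nl_to must differ")
        if not (0 < self.reference_nl_to < self.reference_nl_from):
            raise ValueError("need 0 < reference_nl_to < reference_nl_from")
        if self.baseline_nl < 1:
            raise ValueError("baseline_nl must be >= 1")
        ratios = dict(self.category_ratio)
        for c in VOCategory:
            if c not in ratios:
                raise ValueError(f"category_ratio missing {c}")
            if not (0.0 <= ratios[c] <= 1.0):
                raise ValueError(f"ratio for {c} must be in [0, 1]")
        object.__setattr__(self, "category_ratio", ratios)
        object.__setattr__(self, "segmentation", tuple(sorted(set(self.segmentation))))


def calibrate_slopes(spec: CalibrationSpec) -> Dict[VOCategory, float]:
    """Per-category quality slopes in QALY/patient per additional location.

    The high slope follows from the reference concentration anchor:
    gain / (nl_from - nl_to), negated because quality falls as locations are
    added.  Other categories are fixed fractions of it.
    """
    span = spec.reference_nl_from - spec.reference_nl_to
    if span == 0:
        raise DegenerateAnchorError("anchor span is zero")
    high = -spec.reference_gain_qaly / span
    return {c: spec.category_ratio[c] * high for c in VOCategory}


def _knots(spec: CalibrationSpec, max_sites: int) -> List[int]:
    ks = sorted({k for k in (*spec.segmentation, 1, max_sites) if 1 <= k <= max_sites})
    if ks[0] != 1:
        ks.insert(0, 1)
    if ks[-1] != max_sites:
        ks.append(max_sites)
    return ks


def build_quality_function(
    group: DiagnosisGroup,
    spec: CalibrationSpec,
    max_sites: int,
    convex_factor: float = 1.0,
) -> QualityFunction:
    """Build the piecewise-linear quality function for ``group`` on [1, max_sites].

    The default build (``convex_factor=1``) puts the category slope on every
    segment, with the intercept chosen so that quality gain is zero at
    ``spec.baseline_nl`` (clipped into the domain).  A ``convex_factor > 1``
    steepens segments lying at or below ``reference_nl_to``, approximating the
    convex shape of real volume-outcome curves while keeping the function
    continuous at the knots and still zero at the baseline.
    """
    if max_sites < 1:
        raise ValueError("max_sites must be >= 1")
    if convex_factor < 1.0:
        raise ValueError("convex_factor must be >= 1")
    base_slope = calibrate_slopes(spec)[group.vo_category]
    knots = _knots(spec, max_sites)
    if len(knots) == 1:  # max_sites == 1: single degenerate segment
        intervals = [(1, 1)]
    else:
        intervals = list(zip(knots[:-1], knots[1:]))

    slopes = []
    for lo, hi in intervals:
        s = base_slope
        if convex_factor > 1.0 and hi <= spec.reference_nl_to:
            s = base_slope * convex_factor
        slopes.append(s)

    # Chain intercepts for continuity, anchored at zero gain at the baseline.
    anchor = min(max(spec.baseline_nl, 1), max_sites)
    values = {knots[0]: 0.0}
    for (lo, hi), s in zip(intervals, slopes):
        values[hi] = values[lo] + s * (hi - lo)

    def value_at(nl: float) -> float:
        for (lo, hi), s in zip(intervals, slopes):
            if lo <= nl <= hi:
                return values[lo] + s * (nl - lo)
        raise OutOfDomainError(f"NL={nl} outside [1, {max_sites}]")

    shift = value_at(anchor)
    segments = tuple(
        QualitySegment(lo, hi, s, values[lo] - shift - s * lo)
        for (lo, hi), s in zip(intervals, slopes)
    )
    return QualityFunction(group_id=group.id, segments=segments)


def build_quality_functions(
    groups: Sequence[DiagnosisGroup],
    spec: CalibrationSpec,
    max_sites: int,
    convex_factor: float = 1.0,
) -> Dict[int, QualityFunction]:
    """Quality functions for every group, keyed by group id."""
    return {g.id: build_quality_function(g, spec, max_sites, convex_factor)
            for g in groups}


def evaluate_quality_eur(
    group: DiagnosisGroup,
    qf: QualityFunction,
    nl: int,
    euros_per_qaly: float,
) -> float:
    """Monetized annual quality for ``group`` at ``nl`` locations:
    EQ * NP_d * (a_d * nl + b_d), using the segment whose interval contains nl."""
    try:
        per_patient = qf.evaluate(nl)
    except ValueError as exc:
        raise OutOfDomainError(str(exc)) from exc
    return euros_per_qaly * group.n_patients * per_patient
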