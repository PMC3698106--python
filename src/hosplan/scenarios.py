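"""Sensitivity sweeps and reporting: the what-if layer over the optimizer.

Reproduces the analysis pattern of the allocation study at whatever scale the
instance provides: sweeping the euro-per-QALY rate to see how optimal location
counts respond, reporting patient-weighted travel times by care class against
the everything-open baseline, and tabulating labeled scenarios side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .domain import Instance, Solution, SolverStatus
from .optimizer import SolveOptions, solve_with_refinement

__all__ = [
    "SweepResult",
    "SweepInfeasibleError",
    "eq_sweep",
    "TravelReport",
    "travel_report",
    "compare_landscapes",
    "plot_sweep",
    "plot_travel_report",
]

DEFAULT_EQ_VALUES: Tuple[float, ...] = (20_000.0, 50_000.0, 100_000.0)


class SweepInfeasibleError(RuntimeError):
    """A sub-solve of the sweep came back infeasible."""

    def __init__(self, eq: float, diagnostics: dict):
        self.eq = eq
        self.diagnostics = diagnostics
        super().__init__(f"sweep infeasible at EQ={eq:g}: {diagnostics}")


@dataclass
class SweepResult:
    """Optimal location counts, travel statistics and objectives across a
    range of euro-per-QALY values."""

    eq_values: List[float]
    group_ids: List[int]
    n_locations: np.ndarray          # (n_groups, n_eq)
    travel_minutes_mean: pd.DataFrame  # rows: care class + 'overall'; cols: eq
    objectives: List[float]
    quality_qaly: List[float]        # total quality in QALYs per eq value
    solutions: List[Solution] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-group location counts: one row per (group, eq)."""
        rows = [
            {"group_id": g, "eq": eq, "n_locations": int(self.n_locations[i, j])}
            for i, g in enumerate(self.group_ids)
            for j, eq in enumerate(self.eq_values)
        ]
        return pd.DataFrame(rows)


def _with_eq(instance: Instance, eq: float) -> Instance:
    cfg = dc_replace(instance.config, euros_per_qaly=eq)
    return Instance(
        groups=instance.groups,
        zips=instance.zips,
        sites=instance.sites,
        travel=instance.travel,
        demand=instance.demand,
        quality_functions=instance.quality_functions,
        colocate_pairs=instance.colocate_pairs,
        config=cfg,
    )


def eq_sweep(
    instance: Instance,
    eq_values: Sequence[float] = DEFAULT_EQ_VALUES,
    options: Optional[SolveOptions] = None,
) -> SweepResult:
    """Re-solve the instance at each euro-per-QALY value.

    Records per-group location counts, demand-weighted travel means per care
    class, the objective and total quality in QALYs for every EQ.  Aborts with
    :class:`SweepInfeasibleError` naming the offending EQ if any sub-solve is
    infeasible.  (The bundled HiGHS backend does not support warm starts, so
    each EQ is solved cold.)
    """
    if not eq_values:
        raise ValueError("eq_values must be non-empty")
    nG = instance.n_groups
    nl = np.zeros((nG, len(eq_values)), dtype=np.int64)
    objectives: List[float] = []
    quality_qaly: List[float] = []
    solutions: List[Solution] = []
    travel_cols = {}
    for j, eq in enumerate(eq_values):
        inst = _with_eq(instance, float(eq))
        sol, _ = solve_with_refinement(inst, options=options)
        if sol.solver_status in (SolverStatus.INFEASIBLE, SolverStatus.ERROR):
            raise SweepInfeasibleError(float(eq), sol.diagnostics)
        nl[:, j] = sol.n_locations
        objectives.append(sol.objective_eur)
        quality_qaly.append(float(np.sum(sol.quality_eur)) / float(eq))
        solutions.append(sol)
        rep = travel_report(inst, sol)
        travel_cols[float(eq)] = rep.mean_minutes
    travel_df = pd.DataFrame(travel_cols)
    return SweepResult(
        eq_values=[float(e) for e in eq_values],
        group_ids=[g.id for g in instance.groups],
        n_locations=nl,
        travel_minutes_mean=travel_df,
        objectives=objectives,
        quality_qaly=quality_qaly,
        solutions=solutions,
    )


@dataclass
class TravelReport:
    """Patient-visit-weighted one-way travel minutes by care class, with the
    everything-open nearest-site baseline for comparison."""

    mean_minutes: pd.Series      # index: care classes present + 'overall'
    baseline_minutes: pd.Series  # same index, all candidate sites open
    weights: pd.Series           # total visit weight per care class

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_minutes": self.mean_minutes,
            "baseline_minutes": self.baseline_minutes,
            "visit_weight": self.weights,
        })


def travel_report(instance: Instance, solution: Solution) -> TravelReport:
    """Demand-weighted travel statistics for a feasible solution.

    Weights are patient counts times visits per patient (NPD * NV), so the
    means reflect trips actually made.  One-way minutes are reported; the
    objective's euro terms use round trips.
    """
    tt = instance.travel.minutes
    classes = sorted({g.care_class for g in instance.groups}, key=lambda c: c.value)
    w_sum: Dict[str, float] = {c.value: 0.0 for c in classes}
    wt_sum: Dict[str, float] = {c.value: 0.0 for c in classes}
    wb_sum: Dict[str, float] = {c.value: 0.0 for c in classes}
    nearest_all = tt.min(axis=1)  # baseline: every candidate site open
    for d, g in enumerate(instance.groups):
        w = instance.demand[:, d] * g.n_visits
        a = solution.assign[:, d]
        mask = a >= 0
        minutes = tt[np.nonzero(mask)[0], a[mask]]
        cls = g.care_class.value
        w_sum[cls] += float(w[mask].sum())
        wt_sum[cls] += float((w[mask] * minutes).sum())
        wb_sum[cls] += float((w * nearest_all).sum())
    mean = {c: (wt_sum[c] / w_sum[c] if w_sum[c] > 0 else np.nan) for c in w_sum}
    base = {c: (wb_sum[c] / w_sum[c] if w_sum[c] > 0 else np.nan) for c in w_sum}
    tot_w = sum(w_sum.values())
    mean["overall"] = sum(wt_sum.values()) / tot_w if tot_w > 0 else np.nan
    base["overall"] = sum(wb_sum.values()) / tot_w if tot_w > 0 else np.nan
    w_sum["overall"] = tot_w
    idx = [c.value for c in classes] + ["overall"]
    return TravelReport(
        mean_minutes=pd.Series(mean).reindex(idx),
        baseline_minutes=pd.Series(base).reindex(idx),
        weights=pd.Series(w_sum).reindex(idx),
    )


def compare_landscapes(
    instance: Instance,
    solutions: Union[Mapping[str, Solution], Iterable[Tuple[str, Solution]]],
) -> pd.DataFrame:
    """Tidy comparison of labeled scenarios: per-group location counts and
    euro components, plus a 'total' row per scenario."""
    if isinstance(solutions, Mapping):
        items = list(solutions.items())
    else:
        items = list(solutions)
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate scenario labels")
    rows = []
    for label, sol in items:
        for d, g in enumerate(instance.groups):
            rows.append({
                "scenario": label,
                "group_id": g.id,
                "n_locations": int(sol.n_locations[d]),
                "quality_eur": float(sol.quality_eur[d]),
                "travel_eur": float(sol.travel_eur[d]),
                "objective_eur": float(sol.quality_eur[d] - sol.travel_eur[d]),
            })
        rows.append({
            "scenario": label,
            "group_id": "total",
            "n_locations": int(sol.n_locations.sum()),
            "quality_eur": float(sol.quality_eur.sum()),
            "travel_eur": float(sol.travel_eur.sum()),
            "objective_eur": float(sol.objective_eur),
        })
    return pd.DataFrame(rows)


def plot_sweep(sweep: SweepResult, path: str) -> None:
    """Optimal location count per group across EQ values (one line per group)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for i, gid in enumerate(sweep.group_ids):
        ax.plot(sweep.eq_values, sweep.n_locations[i], marker="o", lw=1,
                alpha=0.6, label=str(gid))
    ax.set_xlabel("euros per QALY")
    ax.set_ylabel("optimal number of locations")
    if len(sweep.group_ids) <= 12:
        ax.legend(title="group", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_travel_report(report: TravelReport, path: str) -> None:
    """Bar chart of mean one-way travel minutes by care class, solution vs
    all-open baseline."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.to_frame()
    x = np.arange(len(df.index))
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(x - 0.2, df["mean_minutes"], width=0.4, label="solution")
    ax.bar(x + 0.2, df["baseline_minutes"], width=0.4, label="all sites open")
    ax.set_xticks(x, df.index)
    ax.set_ylabel("mean one-way travel (min)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
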