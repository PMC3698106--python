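"""Instance-bundle and solution serialization.

An instance is stored as a directory of plain CSV files plus a JSON config:

====================  =====================================================
groups.csv            id, name, care_class, vo_category, n_patients,
                      n_visits, max_travel_min, annual_cost_meur
zips.csv              id, x_km, y_km, population
sites.csv             id, x_km, y_km, from_existing_hospital
traveltime.csv        zip_id + one column per site id (one-way minutes)
demand.csv            zip_id + one column per group id (patients/year)
usage.csv             group_id, facility, units_per_patient
                      (OR: hours; WARD/ICU: bed-days)
quality.csv           group_id, nl_lo, nl_hi, slope, intercept
config.json           schema_version, economic config, facilities,
                      colocate_pairs
====================  =====================================================

All monetary amounts are euros, travel times minutes, both as floats.
Readers raise distinct error kinds naming the file (and cell, where it
applies) on schema violations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .domain import (
    CandidateSite,
    CareClass,
    DiagnosisGroup,
    Facility,
    FacilityType,
    Instance,
    ModelConfig,
    QualityFunction,
    QualitySegment,
    Solution,
    SolverStatus,
    TravelTimeMatrix,
    UtilizationMode,
    VOCategory,
    ZipArea,
)

__all__ = [
    "SCHEMA_VERSION",
    "InstanceIOError",
    "MissingFileError",
    "SchemaError",
    "ConservationError",
    "write_instance",
    "read_instance",
    "write_solution",
    "read_solution",
    "RunManifest",
    "write_manifest",
]

SCHEMA_VERSION = 1


class InstanceIOError(ValueError):
    """Base class for bundle I/O problems."""


class MissingFileError(InstanceIOError):
    pass


class SchemaError(InstanceIOError):
    def __init__(self, file: str, message: str, column: Optional[str] = None,
                 row: Optional[object] = None):
        self.file, self.column, self.row = file, column, row
        loc = file
        if column is not None:
            loc += f", column {column!r}"
        if row is not None:
            loc += f", row {row!r}"
        super().__init__(f"{loc}: {message}")


class ConservationError(InstanceIOError):
    """Per-group demand does not sum to the group's admission count."""


PathLike = Union[str, Path]


def write_instance(instance: Instance, path: PathLike) -> None:
    """Write an instance bundle (see module docstring for the layout)."""
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([
        {
            "id": g.id, "name": g.name, "care_class": g.care_class.value,
            "vo_category": g.vo_category.value, "n_patients": g.n_patients,
            "n_visits": g.n_visits, "max_travel_min": g.max_travel_min,
            "annual_cost_meur": g.annual_cost_meur,
        }
        for g in instance.groups
    ]).to_csv(p / "groups.csv", index=False, float_format="%.17g")
    pd.DataFrame([
        {"id": z.id, "x_km": z.coords[0], "y_km": z.coords[1],
         "population": z.population}
        for z in instance.zips
    ]).to_csv(p / "zips.csv", index=False, float_format="%.17g")
    pd.DataFrame([
        {"id": s.id, "x_km": s.coords[0], "y_km": s.coords[1],
         "from_existing_hospital": int(s.from_existing_hospital)}
        for s in instance.sites
    ]).to_csv(p / "sites.csv", index=False, float_format="%.17g")
    site_ids = [s.id for s in instance.sites]
    tdf = pd.DataFrame(instance.travel.minutes, columns=site_ids)
    tdf.insert(0, "zip_id", [z.id for z in instance.zips])
    tdf.to_csv(p / "traveltime.csv", index=False, float_format="%.17g")
    gcols = [str(g.id) for g in instance.groups]
    ddf = pd.DataFrame(instance.demand, columns=gcols)
    ddf.insert(0, "zip_id", [z.id for z in instance.zips])
    ddf.to_csv(p / "demand.csv", index=False, float_format="%.17g")
    pd.DataFrame([
        {"group_id": g.id, "facility": f.value, "units_per_patient": g.usage[f]}
        for g in instance.groups for f in FacilityType
    ]).to_csv(p / "usage.csv", index=False, float_format="%.17g")
    pd.DataFrame([
        {"group_id": gid, "nl_lo": s.nl_lo, "nl_hi": s.nl_hi,
         "slope": s.slope, "intercept": s.intercept}
        for gid, qf in sorted(instance.quality_functions.items())
        for s in qf.segments
    ]).to_csv(p / "quality.csv", index=False, float_format="%.17g")
    cfg = instance.config
    config = {
        "schema_version": SCHEMA_VERSION,
        "euros_per_qaly": cfg.euros_per_qaly,
        "euros_per_travel_hour": cfg.euros_per_travel_hour,
        "round_trip_factor": cfg.round_trip_factor,
        "big_m": cfg.big_m,
        "mip_gap": cfg.mip_gap,
        "utilization_mode": cfg.utilization_mode.value,
        "facilities": {f.id.value: f.min_utilization for f in cfg.facilities},
        "seed": cfg.seed,
        "max_refinement_iters": cfg.max_refinement_iters,
        "colocate_pairs": [list(pr) for pr in instance.colocate_pairs],
    }
    (p / "config.json").write_text(json.dumps(config, indent=2))


def _read_csv(p: Path, name: str, required: List[str]) -> pd.DataFrame:
    f = p / name
    if not f.exists():
        raise MissingFileError(f"bundle file missing: {f}")
    df = pd.read_csv(f, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise SchemaError(name, "missing column", column=col)
    return df


def read_instance(path: PathLike) -> Instance:
    """Read an instance bundle; the inverse of :func:`write_instance`."""
    p = Path(path)
    cfg_file = p / "config.json"
    if not cfg_file.exists():
        raise MissingFileError(f"bundle file missing: {cfg_file}")
    config_raw = json.loads(cfg_file.read_text())
    version = config_raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError("config.json", f"unsupported schema version {version}")

    gdf = _read_csv(p, "groups.csv",
                    ["id", "name", "care_class", "vo_category", "n_patients",
                     "n_visits", "max_travel_min", "annual_cost_meur"])
    udf = _read_csv(p, "usage.csv", ["group_id", "facility", "units_per_patient"])
    usage: Dict[int, Dict[FacilityType, float]] = {}
    for _, row in udf.iterrows():
        try:
            fac = FacilityType(row["facility"])
        except ValueError:
            raise SchemaError("usage.csv", f"unknown facility {row['facility']!r}",
                              column="facility", row=int(row["group_id"]))
        v = float(row["units_per_patient"])
        if v < 0:
            raise SchemaError("usage.csv", "negative usage",
                              column="units_per_patient", row=int(row["group_id"]))
        usage.setdefault(int(row["group_id"]), {})[fac] = v

    groups = []
    for _, row in gdf.iterrows():
        gid = int(row["id"])
        try:
            groups.append(DiagnosisGroup(
                id=gid,
                name=str(row["name"]),
                care_class=CareClass(row["care_class"]),
                vo_category=VOCategory(row["vo_category"]),
                n_patients=int(row["n_patients"]),
                n_visits=float(row["n_visits"]),
                max_travel_min=float(row["max_travel_min"]),
                usage=usage.get(gid, {}),
                annual_cost_meur=float(row["annual_cost_meur"]),
            ))
        except ValueError as exc:
            raise SchemaError("groups.csv", str(exc), row=gid)

    zdf = _read_csv(p, "zips.csv", ["id", "x_km", "y_km", "population"])
    zips = []
    for _, row in zdf.iterrows():
        try:
            zips.append(ZipArea(id=str(row["id"]),
                                population=float(row["population"]),
                                coords=(float(row["x_km"]), float(row["y_km"]))))
        except ValueError as exc:
            raise SchemaError("zips.csv", str(exc), row=str(row["id"]))

    sdf = _read_csv(p, "sites.csv", ["id", "x_km", "y_km", "from_existing_hospital"])
    sites = [
        CandidateSite(id=str(row["id"]),
                      coords=(float(row["x_km"]), float(row["y_km"])),
                      from_existing_hospital=bool(int(row["from_existing_hospital"])))
        for _, row in sdf.iterrows()
    ]

    tdf = _read_csv(p, "traveltime.csv", ["zip_id"])
    site_ids = [s.id for s in sites]
    for sid in site_ids:
        if sid not in tdf.columns:
            raise SchemaError("traveltime.csv", "missing site column", column=sid)
    tmat = tdf[site_ids].to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(tmat) | (tmat < 0))
    if bad.size:
        r, c = bad[0]
        raise SchemaError("traveltime.csv", f"invalid travel time {tmat[r, c]!r}",
                          column=site_ids[c], row=str(tdf["zip_id"].iloc[r]))

    ddf = _read_csv(p, "demand.csv", ["zip_id"])
    gcols = [str(g.id) for g in groups]
    for gc in gcols:
        if gc not in ddf.columns:
            raise SchemaError("demand.csv", "missing group column", column=gc)
    demand = ddf[gcols].to_numpy(dtype=float)
    if np.any(demand < 0):
        r, c = np.argwhere(demand < 0)[0]
        raise SchemaError("demand.csv", "negative demand", column=gcols[c],
                          row=str(ddf["zip_id"].iloc[r]))
    sums = demand.sum(axis=0)
    for d, g in enumerate(groups):
        if abs(sums[d] - g.n_patients) > 1.0:
            raise ConservationError(
                f"demand.csv: group {g.id} demand sums to {sums[d]}, "
                f"expected {g.n_patients}")

    qdf = _read_csv(p, "quality.csv",
                    ["group_id", "nl_lo", "nl_hi", "slope", "intercept"])
    qfs: Dict[int, QualityFunction] = {}
    for gid, sub in qdf.groupby("group_id"):
        sub = sub.sort_values("nl_lo")
        segments = tuple(
            QualitySegment(int(r["nl_lo"]), int(r["nl_hi"]),
                           float(r["slope"]), float(r["intercept"]))
            for _, r in sub.iterrows()
        )
        try:
            qfs[int(gid)] = QualityFunction(group_id=int(gid), segments=segments)
        except ValueError as exc:
            raise SchemaError("quality.csv", str(exc), row=int(gid))

    facilities = tuple(
        Facility(FacilityType(k), float(v))
        for k, v in config_raw.get("facilities", {}).items()
    )
    config = ModelConfig(
        euros_per_qaly=float(config_raw["euros_per_qaly"]),
        euros_per_travel_hour=float(config_raw["euros_per_travel_hour"]),
        round_trip_factor=float(config_raw.get("round_trip_factor", 2.0)),
        big_m=float(config_raw.get("big_m", 1e6)),
        mip_gap=float(config_raw.get("mip_gap", 1e-6)),
        utilization_mode=UtilizationMode(config_raw.get("utilization_mode",
                                                        "conditional")),
        facilities=facilities,
        seed=int(config_raw.get("seed", 0)),
        max_refinement_iters=int(config_raw.get("max_refinement_iters", 10)),
    )
    pairs = [tuple(pr) for pr in config_raw.get("colocate_pairs", [])]
    return Instance(
        groups=groups,
        zips=zips,
        sites=sites,
        travel=TravelTimeMatrix(minutes=tmat),
        demand=demand,
        quality_functions=qfs,
        colocate_pairs=pairs,
        config=config,
    )


# ---------------------------------------------------------------------------
# Solutions
# ---------------------------------------------------------------------------

def write_solution(sol: Solution, path: PathLike,
                   instance: Optional[Instance] = None) -> None:
    """Serialize a solution to JSON.  When the instance is given, site and
    group labels are stored alongside the index arrays."""
    doc = {
        "solver_status": sol.solver_status.value,
        "gap": None if not np.isfinite(sol.gap) else sol.gap,
        "objective_eur": None if not np.isfinite(sol.objective_eur)
                         else sol.objective_eur,
        "open_sites": sol.open_sites.tolist(),
        "offers": sol.offers.tolist(),
        "assign": sol.assign.tolist(),
        "n_locations": sol.n_locations.tolist(),
        "quality_eur": sol.quality_eur.tolist(),
        "travel_eur": sol.travel_eur.tolist(),
        "diagnostics": sol.diagnostics,
    }
    if instance is not None:
        doc["site_ids"] = [s.id for s in instance.sites]
        doc["group_ids"] = [g.id for g in instance.groups]
        doc["zip_ids"] = [z.id for z in instance.zips]
    Path(path).write_text(json.dumps(doc))


def read_solution(path: PathLike) -> Solution:
    doc = json.loads(Path(path).read_text())
    obj = doc["objective_eur"]
    gap = doc["gap"]
    return Solution(
        open_sites=np.array(doc["open_sites"], dtype=np.int8),
        offers=np.array(doc["offers"], dtype=np.int8),
        assign=np.array(doc["assign"], dtype=np.int64),
        n_locations=np.array(doc["n_locations"], dtype=np.int64),
        quality_eur=np.array(doc["quality_eur"]),
        travel_eur=np.array(doc["travel_eur"]),
        objective_eur=float("-inf") if obj is None else float(obj),
        solver_status=SolverStatus(doc["solver_status"]),
        gap=float("inf") if gap is None else float(gap),
        diagnostics=doc.get("diagnostics", {}),
    )


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def _bundle_hashes(path: Path) -> Dict[str, str]:
    out = {}
    for f in sorted(path.iterdir()):
        if f.is_file():
            out[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    return out


@dataclasses.dataclass
class RunManifest:
    """Record of one solve: config snapshot, seed, input hashes, backend and
    output paths.  Re-running with the same inputs and seed reproduces the
    outputs."""

    config: dict
    seed: int
    input_hashes: Dict[str, str]
    solver_backend: str
    timestamp: str
    solution_path: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def write_manifest(
    instance_path: PathLike,
    instance: Instance,
    solution_path: PathLike,
    manifest_path: PathLike,
) -> RunManifest:
    cfg = instance.config
    manifest = RunManifest(
        config={
            "euros_per_qaly": cfg.euros_per_qaly,
            "euros_per_travel_hour": cfg.euros_per_travel_hour,
            "round_trip_factor": cfg.round_trip_factor,
            "utilization_mode": cfg.utilization_mode.value,
            "mip_gap": cfg.mip_gap,
        },
        seed=cfg.seed,
        input_hashes=_bundle_hashes(Path(instance_path)),
        solver_backend="scipy-highs",
        timestamp=datetime.now(timezone.utc).isoformat(),
        solution_path=str(solution_path),
    )
    Path(manifest_path).write_text(manifest.to_json())
    return manifest
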