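"""Plain-text readers and writers for the documented exchange formats.

* trace CSV        — ``t_s,lr_mm,cc_mm,ap_mm``
* RPM CSV          — ``t_s,ext_mm,gate_on`` (gate_on in {0, 1})
* projections CSV  — ``t_s,angle_deg,marker_id,u_mm,v_mm,detected``
* spot plan JSON   — fields, layers, spots, MU
* ECM model JSON
* config YAML      — blocks ``breathing:``, ``cbct:``, ``gating:``
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import yaml

from .cbct import ProjectionSet, ScannerGeometry
from .delivery import GatingConfig
from .dose import SpotPlan
from .ecm import EcmModel
from .motion import BreathingParams
from .traces import RpmTrace, Trace3D

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_rpm_csv", "read_rpm_csv",
    "write_projections_csv", "read_projections_csv",
    "write_plan_json", "read_plan_json",
    "write_ecm_json", "read_ecm_json",
    "load_config",
]


def write_trace_csv(trace: Trace3D, path) -> None:
    pd.DataFrame(
        {
            "t_s": trace.t,
            "lr_mm": trace.pos[:, 0],
            "cc_mm": trace.pos[:, 1],
            "ap_mm": trace.pos[:, 2],
        }
    ).to_csv(path, index=False)


def read_trace_csv(path) -> Trace3D:
    df = pd.read_csv(path)
    return Trace3D(df["t_s"].to_numpy(), df[["lr_mm", "cc_mm", "ap_mm"]].to_numpy())


def write_rpm_csv(rpm: RpmTrace, path) -> None:
    pd.DataFrame(
        {"t_s": rpm.t, "ext_mm": rpm.ext, "gate_on": rpm.gate_on.astype(int)}
    ).to_csv(path, index=False)


def read_rpm_csv(path) -> RpmTrace:
    df = pd.read_csv(path)
    return RpmTrace(
        df["t_s"].to_numpy(),
        df["ext_mm"].to_numpy(),
        df["gate_on"].to_numpy().astype(bool),
    )


def write_projections_csv(proj: ProjectionSet, path) -> None:
    n, m = proj.t.size, proj.n_markers
    rows = {
        "t_s": np.repeat(proj.t, m),
        "angle_deg": np.repeat(proj.angle_deg, m),
        "marker_id": np.tile(np.arange(m), n),
        "u_mm": proj.uv_mm[:, :, 0].ravel(),
        "v_mm": proj.uv_mm[:, :, 1].ravel(),
        "detected": proj.detected.astype(int).ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def read_projections_csv(path) -> ProjectionSet:
    df = pd.read_csv(path)
    t = np.unique(df["t_s"].to_numpy())
    markers = np.unique(df["marker_id"].to_numpy())
    n, m = t.size, markers.size
    uv = np.full((n, m, 2), np.nan)
    det = np.zeros((n, m), dtype=bool)
    t_index = {v: i for i, v in enumerate(t)}
    angle = np.empty(n)
    for _, row in df.iterrows():
        i = t_index[row["t_s"]]
        j = int(row["marker_id"])
        angle[i] = row["angle_deg"]
        uv[i, j] = (row["u_mm"], row["v_mm"])
        det[i, j] = bool(row["detected"])
    uv[~det] = np.nan
    return ProjectionSet(t, angle, uv, det)


def write_plan_json(plan: SpotPlan, path) -> None:
    d = {
        "gantry_angles_deg": plan.gantry_angles_deg.tolist(),
        "prescription_gy": plan.prescription_gy,
        "n_fractions": plan.n_fractions,
        "e_min_mev": plan.e_min_mev,
        "e_max_mev": plan.e_max_mev,
        "spots": {
            "field": plan.field.tolist(),
            "layer": plan.layer.tolist(),
            "energy_mev": plan.energy_mev.tolist(),
            "x_bev_mm": plan.x_bev.tolist(),
            "y_bev_mm": plan.y_bev.tolist(),
            "mu": plan.mu.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(d, fh)


def read_plan_json(path) -> SpotPlan:
    with open(path) as fh:
        d = json.load(fh)
    s = d["spots"]
    return SpotPlan(
        field=np.asarray(s["field"], dtype=int),
        layer=np.asarray(s["layer"], dtype=int),
        energy_mev=np.asarray(s["energy_mev"], dtype=float),
        x_bev=np.asarray(s["x_bev_mm"], dtype=float),
        y_bev=np.asarray(s["y_bev_mm"], dtype=float),
        mu=np.asarray(s["mu"], dtype=float),
        gantry_angles_deg=np.asarray(d["gantry_angles_deg"], dtype=float),
        e_min_mev=d.get("e_min_mev", 71.0),
        e_max_mev=d.get("e_max_mev", 153.0),
        prescription_gy=d.get("prescription_gy", 58.0),
        n_fractions=d.get("n_fractions", 15),
    )


def write_ecm_json(model: EcmModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def read_ecm_json(path) -> EcmModel:
    with open(path) as fh:
        return EcmModel.from_dict(json.load(fh))


def load_config(path) -> dict:
    """Parse a YAML config with optional ``breathing``, ``cbct`` and
    ``gating`` blocks into parameter objects."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = dict(raw)
    if "breathing" in raw:
        b = dict(raw["breathing"])
        for key in ("amp_mm", "drift_mm_per_min"):
            if key in b:
                b[key] = tuple(b[key])
        out["breathing"] = BreathingParams(**b)
    if "cbct" in raw:
        out["cbct"] = ScannerGeometry(**raw["cbct"])
    if "gating" in raw:
        out["gating"] = GatingConfig(**raw["gating"])
    return out
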