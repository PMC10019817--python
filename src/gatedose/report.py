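"""Geometric and dosimetric fraction metrics and report assembly.

Implements the per-fraction metrics used to characterize gated
delivery: exhale statistics (the exhale period is the time within the
95th-100th percentile of the CC marker position), baseline drift of the
exhale position between the setup and post-treatment cone-beam scans,
the online registration error, tumor motion ranges (98th minus 2nd
percentile) during beam-on and over the full field duration, per-spot
treatment-error statistics and the CTV DVH metrics of the planned and
reconstructed doses.

All percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose import DvhMetrics
from .traces import AXES, CC, Trace3D

__all__ = [
    "exhale_mask",
    "exhale_position",
    "baseline_drift",
    "online_registration_error",
    "motion_range",
    "TreatmentErrorStats",
    "treatment_error_stats",
    "FractionReport",
    "build_fraction_report",
    "summarize_fractions",
]


def exhale_mask(trace: Trace3D, exhale_is_max: bool = True) -> np.ndarray:
    """True where the CC position is in its exhale-side 5% tail.

    With the package convention (exhale = cranial extreme) this is the
    95th-100th percentile of the CC coordinate; set ``exhale_is_max``
    False for the opposite sign convention.
    """
    cc = trace.pos[:, CC]
    valid = np.isfinite(cc)
    if not valid.any():
        raise ValueError("trace has no valid samples")
    if exhale_is_max:
        thr = np.percentile(cc[valid], 95.0)
        return valid & (cc >= thr)
    thr = np.percentile(cc[valid], 5.0)
    return valid & (cc <= thr)


def exhale_position(trace: Trace3D, exhale_is_max: bool = True) -> np.ndarray:
    """Mean position (mm) over the exhale period, per direction."""
    m = exhale_mask(trace, exhale_is_max)
    return trace.pos[m].mean(axis=0)


def baseline_drift(setup_trace: Trace3D, post_trace: Trace3D, **kw) -> np.ndarray:
    """Drift of the exhale position from the setup scan to the post scan."""
    return exhale_position(post_trace, **kw) - exhale_position(setup_trace, **kw)


def online_registration_error(trajectory_setup, online_match) -> np.ndarray:
    """Difference between the retrospective trajectory-based setup and the
    couch correction applied from the online 3D/3D registration."""
    return np.asarray(trajectory_setup, dtype=float) - np.asarray(online_match, dtype=float)


def motion_range(trace: Trace3D, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-direction 98th-minus-2nd-percentile motion range (mm)."""
    pos = trace.pos
    if mask is not None:
        pos = pos[np.asarray(mask, dtype=bool)]
    pos = pos[np.all(np.isfinite(pos), axis=1)]
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 samples to compute a motion range")
    return np.percentile(pos, 98.0, axis=0) - np.percentile(pos, 2.0, axis=0)


@dataclass
class TreatmentErrorStats:
    """Per-spot tumor-position error statistics relative to the plan."""

    mean_mm: np.ndarray
    sd_mm: np.ndarray
    rms_mm: np.ndarray
    mean_3d_mm: float
    sd_3d_mm: float

    def to_dict(self) -> dict:
        return {
            "mean_mm": self.mean_mm.tolist(),
            "sd_mm": self.sd_mm.tolist(),
            "rms_mm": self.rms_mm.tolist(),
            "mean_3d_mm": self.mean_3d_mm,
            "sd_3d_mm": self.sd_3d_mm,
        }


def treatment_error_stats(
    per_spot_positions: np.ndarray, planned_position=(0.0, 0.0, 0.0)
) -> TreatmentErrorStats:
    """Mean, SD and RMS error per direction plus 3D-error statistics."""
    p = np.asarray(per_spot_positions, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] == 0:
        raise ValueError("need a non-empty (n, 3) array of spot positions")
    err = p - np.asarray(planned_position, dtype=float)
    norms = np.linalg.norm(err, axis=1)
    return TreatmentErrorStats(
        mean_mm=err.mean(axis=0),
        sd_mm=err.std(axis=0, ddof=0),
        rms_mm=np.sqrt(np.mean(err**2, axis=0)),
        mean_3d_mm=float(norms.mean()),
        sd_3d_mm=float(norms.std(ddof=0)),
    )


@dataclass
class FractionReport:
    """All geometric and dosimetric metrics of one treatment fraction."""

    online_registration_error_mm: np.ndarray
    baseline_drift_mm: np.ndarray
    ecm_rms_mm: np.ndarray
    treatment_error: TreatmentErrorStats
    motion_range_beam_on_mm: np.ndarray
    motion_range_full_mm: np.ndarray
    dvh_planned: DvhMetrics | None = None
    dvh_reconstructed: DvhMetrics | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "online_registration_error_mm": np.asarray(self.online_registration_error_mm).tolist(),
            "baseline_drift_mm": np.asarray(self.baseline_drift_mm).tolist(),
            "ecm_rms_mm": np.asarray(self.ecm_rms_mm).tolist(),
            "treatment_error": self.treatment_error.to_dict(),
            "motion_range_beam_on_mm": np.asarray(self.motion_range_beam_on_mm).tolist(),
            "motion_range_full_mm": np.asarray(self.motion_range_full_mm).tolist(),
            "dvh_planned": self.dvh_planned.to_dict() if self.dvh_planned else None,
            "dvh_reconstructed": (
                self.dvh_reconstructed.to_dict() if self.dvh_reconstructed else None
            ),
        }
        d.update(self.extras)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FractionReport":
        with open(path) as fh:
            d = json.load(fh)
        te = d["treatment_error"]
        known = {
            "online_registration_error_mm",
            "baseline_drift_mm",
            "ecm_rms_mm",
            "treatment_error",
            "motion_range_beam_on_mm",
            "motion_range_full_mm",
            "dvh_planned",
            "dvh_reconstructed",
        }

        def dvh(x):
            if x is None:
                return None
            return DvhMetrics(x["D98_gy"], x["D50_gy"], x["D2_gy"], x["HI_pct"], x["mean_gy"])

        return cls(
            online_registration_error_mm=np.asarray(d["online_registration_error_mm"]),
            baseline_drift_mm=np.asarray(d["baseline_drift_mm"]),
            ecm_rms_mm=np.asarray(d["ecm_rms_mm"]),
            treatment_error=TreatmentErrorStats(
                mean_mm=np.asarray(te["mean_mm"]),
                sd_mm=np.asarray(te["sd_mm"]),
                rms_mm=np.asarray(te["rms_mm"]),
                mean_3d_mm=te["mean_3d_mm"],
                sd_3d_mm=te["sd_3d_mm"],
            ),
            motion_range_beam_on_mm=np.asarray(d["motion_range_beam_on_mm"]),
            motion_range_full_mm=np.asarray(d["motion_range_full_mm"]),
            dvh_planned=dvh(d.get("dvh_planned")),
            dvh_reconstructed=dvh(d.get("dvh_reconstructed")),
            extras={k: v for k, v in d.items() if k not in known},
        )


_REQUIRED = {
    "online_registration_error_mm": "setup registration",
    "baseline_drift_mm": "baseline drift",
    "ecm_rms_mm": "correlation-model fit",
    "treatment_error": "per-spot treatment error",
    "motion_range_beam_on_mm": "gated motion range",
    "motion_range_full_mm": "full motion range",
}


def build_fraction_report(**artifacts) -> FractionReport:
    """Assemble a fraction report; raises naming the missing stage if a
    required artifact is absent."""
    for key, stage in _REQUIRED.items():
        if artifacts.get(key) is None:
            raise ValueError(f"missing artifact '{key}' from stage: {stage}")
    return FractionReport(
        online_registration_error_mm=np.asarray(artifacts["online_registration_error_mm"]),
        baseline_drift_mm=np.asarray(artifacts["baseline_drift_mm"]),
        ecm_rms_mm=np.asarray(artifacts["ecm_rms_mm"]),
        treatment_error=artifacts["treatment_error"],
        motion_range_beam_on_mm=np.asarray(artifacts["motion_range_beam_on_mm"]),
        motion_range_full_mm=np.asarray(artifacts["motion_range_full_mm"]),
        dvh_planned=artifacts.get("dvh_planned"),
        dvh_reconstructed=artifacts.get("dvh_reconstructed"),
        extras=artifacts.get("extras", {}),
    )


def summarize_fractions(reports: list[FractionReport]) -> pd.DataFrame:
    """Series-level mean +/- SD table over fractions, one row per metric
    and one column per motion direction."""
    if not reports:
        raise ValueError("no fraction reports")
    rows = {}
    per_dir_metrics = {
        "online registration error": [r.online_registration_error_mm for r in reports],
        "baseline drift": [r.baseline_drift_mm for r in reports],
        "RMS error of ECM fit": [r.ecm_rms_mm for r in reports],
        "treatment error during beam-on": [r.treatment_error.mean_mm for r in reports],
        "motion range during beam-on": [r.motion_range_beam_on_mm for r in reports],
        "full motion range": [r.motion_range_full_mm for r in reports],
    }
    for name, vals in per_dir_metrics.items():
        arr = np.asarray(vals, dtype=float)
        for k, ax in enumerate(AXES):
            rows.setdefault(name, {})[f"{ax}_mean_mm"] = arr[:, k].mean()
            rows[name][f"{ax}_sd_mm"] = arr[:, k].std(ddof=0)
    return pd.DataFrame(rows).T
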