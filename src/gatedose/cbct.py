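"""Cone-beam acquisition model: point-source projection of fiducial markers.

The gantry rotates about the CC (y) axis.  At gantry angle 0 the source
sits anterior of the patient at distance ``sad_mm`` from the isocenter
and the beam points in the -AP direction.  The flat panel is centered on
the beam axis at ``sid_mm`` from the source; its ``u`` axis is
horizontal in the gantry frame and its ``v`` axis is parallel to CC.
Panel coordinates are reported in mm at the detector plane, so a point
in the isocenter plane appears magnified by ``sid/sad``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import Trace3D

__all__ = [
    "ScannerGeometry",
    "ProjectionSet",
    "project_point",
    "simulate_cbct",
]


@dataclass
class ScannerGeometry:
    """Cone-beam scanner description (defaults: ProBeam-style imaging system)."""

    sid_mm: float = 3700.0
    sad_mm: float = 2700.0
    pixel_mm: float = 0.388
    arc_deg: float = 360.0
    n_proj: int = 1000
    scan_duration_s: float = 60.0
    start_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sid_mm > self.sad_mm > 0):
            raise ValueError("require sid_mm > sad_mm > 0")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")
        if self.n_proj < 2:
            raise ValueError("need at least two projections")

    @property
    def magnification(self) -> float:
        return self.sid_mm / self.sad_mm

    def axes(self, angle_deg: float):
        """Source position, panel axes and beam direction at a gantry angle.

        Returns ``(source, u_hat, v_hat, beam)`` where ``beam`` is the unit
        vector from source towards the isocenter.
        """
        th = np.deg2rad(angle_deg)
        e = np.array([np.sin(th), 0.0, np.cos(th)])  # iso -> source direction
        source = self.sad_mm * e
        u_hat = np.array([np.cos(th), 0.0, -np.sin(th)])
        v_hat = np.array([0.0, 1.0, 0.0])
        return source, u_hat, v_hat, -e

    def angles(self) -> np.ndarray:
        closed = np.isclose(self.arc_deg % 360.0, 0.0)
        return self.start_angle_deg + np.linspace(
            0.0, self.arc_deg, self.n_proj, endpoint=not closed
        )


@dataclass
class ProjectionSet:
    """Timestamped 2D detections of one or more markers on the panel.

    ``uv_mm`` has shape (n_proj, n_markers, 2); undetected entries are
    NaN and flagged False in ``detected``.
    """

    t: np.ndarray
    angle_deg: np.ndarray
    uv_mm: np.ndarray
    detected: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        self.uv_mm = np.asarray(self.uv_mm, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        n = self.t.size
        if self.angle_deg.size != n:
            raise ValueError("t and angle_deg must have equal length")
        if self.uv_mm.ndim != 3 or self.uv_mm.shape[0] != n or self.uv_mm.shape[2] != 2:
            raise ValueError("uv_mm must have shape (n_proj, n_markers, 2)")
        if self.detected.shape != self.uv_mm.shape[:2]:
            raise ValueError("detected must have shape (n_proj, n_markers)")
        d = np.diff(self.angle_deg)
        if d.size and not (np.all(d >= 0) or np.all(d <= 0)):
            raise ValueError("gantry angles must be monotonic over the arc")

    @property
    def n_markers(self) -> int:
        return self.uv_mm.shape[1]

    def marker(self, j: int) -> "ProjectionSet":
        return ProjectionSet(
            self.t, self.angle_deg, self.uv_mm[:, j : j + 1, :], self.detected[:, j : j + 1]
        )

    def arc_span_deg(self, j: int = 0) -> float:
        m = self.detected[:, j]
        if not m.any():
            return 0.0
        a = self.angle_deg[m]
        return float(a.max() - a.min())


def project_point(geom: ScannerGeometry, angle_deg: float, p3d) -> np.ndarray:
    """Perspective projection of a 3D patient-coordinate point onto the panel."""
    p = np.asarray(p3d, dtype=float)
    source, u_hat, v_hat, _ = geom.axes(angle_deg)
    th = np.deg2rad(angle_deg)
    e = np.array([np.sin(th), 0.0, np.cos(th)])
    w = geom.sad_mm - p @ e  # depth along the beam, measured from the source
    if np.any(w <= 0) or np.any(w >= geom.sid_mm):
        raise ValueError("point must lie strictly between source and panel")
    u = (p @ u_hat) * geom.sid_mm / w
    v = (p @ v_hat) * geom.sid_mm / w
    return np.array([u, v])


def _project_many(geom: ScannerGeometry, angles_deg: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Vectorized projection of pts[i] at angles_deg[i]; returns (n, 2)."""
    th = np.deg2rad(angles_deg)
    e = np.stack([np.sin(th), np.zeros_like(th), np.cos(th)], axis=1)
    u_hat = np.stack([np.cos(th), np.zeros_like(th), -np.sin(th)], axis=1)
    w = geom.sad_mm - np.einsum("ni,ni->n", pts, e)
    if np.any(w <= 0) or np.any(w >= geom.sid_mm):
        raise ValueError("point must lie strictly between source and panel")
    u = np.einsum("ni,ni->n", pts, u_hat) * geom.sid_mm / w
    v = pts[:, 1] * geom.sid_mm / w
    return np.stack([u, v], axis=1)


def simulate_cbct(
    geom: ScannerGeometry,
    traces: list[Trace3D],
    t0_s: float = 0.0,
    noise_sd_px: float = 0.0,
    detect_prob: float = 1.0,
    seed: int | None = None,
) -> ProjectionSet:
    """Emulate a cone-beam acquisition of moving point markers.

    Timestamps and gantry angles are evenly spaced over the arc
    (constant gantry speed).  Each marker is interpolated from its
    trace, projected, perturbed by Gaussian pixel noise and dropped
    with probability ``1 - detect_prob``.
    """
    t_end = t0_s + geom.scan_duration_s
    for tr in traces:
        if tr.t[0] > t0_s + 1e-9 or tr.t[-1] < t_end - 1e-9:
            raise ValueError(
                f"trace covers [{tr.t[0]}, {tr.t[-1]}] s but the scan needs "
                f"[{t0_s}, {t_end}] s"
            )
    angles = geom.angles()
    closed = np.isclose(geom.arc_deg % 360.0, 0.0)
    t = t0_s + np.linspace(0.0, geom.scan_duration_s, geom.n_proj, endpoint=not closed)
    rng = np.random.default_rng(seed)
    n, m = geom.n_proj, len(traces)
    uv = np.full((n, m, 2), np.nan)
    det = np.zeros((n, m), dtype=bool)
    for j, tr in enumerate(traces):
        pts = tr.interp(t)
        uv[:, j, :] = _project_many(geom, angles, pts)
        det[:, j] = True
    if noise_sd_px > 0:
        uv += rng.normal(0.0, noise_sd_px * geom.pixel_mm, size=uv.shape)
    if detect_prob < 1.0:
        drop = rng.random(det.shape) > detect_prob
        det &= ~drop
        uv[~det] = np.nan
    return ProjectionSet(t, angles, uv, det)
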