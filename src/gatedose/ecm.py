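"""Augmented linear external-internal correlation model (ECM).

The internal tumor position in each direction d is modelled from the
external surrogate signal as

    INT_d(t) = A_d * EXT(t) + B_d * EXT(t - tau) + C_d

where the delayed term accounts for hysteresis and phase differences
between internal and external motion.  A, B and C are fitted per
direction by ordinary least squares; the delay tau is shared by all
three directions and selected on a grid by minimizing the total squared
residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import AXES, RpmTrace, Trace3D

__all__ = ["EcmModel", "default_tau_grid", "fit_ecm", "apply_ecm", "rms_error"]


def default_tau_grid(tau_max_s: float = 1.0, step_s: float = 0.04) -> np.ndarray:
    """Delay search grid, 0 to ``tau_max_s`` at the gating-log resolution."""
    n = int(round(tau_max_s / step_s))
    return step_s * np.arange(n + 1)


@dataclass
class EcmModel:
    """Fitted correlation-model coefficients (per direction LR, CC, AP)."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    tau_s: float
    rms_fit_mm: np.ndarray

    def __post_init__(self) -> None:
        for name in ("A", "B", "C", "rms_fit_mm"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            setattr(self, name, v)
        if self.tau_s < 0:
            raise ValueError("tau_s must be non-negative")
        if np.any(self.rms_fit_mm < 0):
            raise ValueError("rms_fit_mm must be non-negative")

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
            "tau_s": float(self.tau_s),
            "rms_fit_mm": self.rms_fit_mm.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EcmModel":
        return cls(
            np.asarray(d["A"]), np.asarray(d["B"]), np.asarray(d["C"]),
            float(d["tau_s"]), np.asarray(d["rms_fit_mm"]),
        )


def _design(ext: RpmTrace, t: np.ndarray, tau: float) -> np.ndarray:
    x_now = ext.interp(t)
    x_lag = ext.interp(t - tau)  # clamps to the first sample for t < tau
    return np.column_stack([x_now, x_lag, np.ones_like(x_now)])


def fit_ecm(
    ext: RpmTrace,
    int3d: Trace3D,
    tau_grid_s: np.ndarray | None = None,
) -> EcmModel:
    """Fit the correlation model from paired external/internal recordings.

    The external signal is linearly interpolated onto the internal
    timestamps.  For every tau on the grid a per-direction OLS fit of
    INT on [EXT(t), EXT(t-tau), 1] is computed; the returned model uses
    the tau minimizing the total squared residual over all directions
    (ties broken towards the smallest tau).
    """
    if tau_grid_s is None:
        tau_grid_s = default_tau_grid()
    tau_grid_s = np.asarray(tau_grid_s, dtype=float)
    if tau_grid_s.size == 0:
        raise ValueError("tau grid must be non-empty")
    if np.any(tau_grid_s < 0):
        raise ValueError("tau grid must be non-negative")

    clean = int3d.dropna()
    m = (clean.t >= ext.t[0]) & (clean.t <= ext.t[-1])
    t = clean.t[m]
    y = clean.pos[m]
    if t.size < 10:
        raise ValueError(f"need at least 10 paired samples, got {t.size}")
    if np.ptp(ext.interp(t)) < 1e-12:
        raise ValueError("degenerate regressor: EXT(t) is constant over the overlap")

    best = None
    for tau in tau_grid_s:
        X = _design(ext, t, tau)
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        ssr = float(np.sum((y - X @ coef) ** 2))
        if best is None or ssr < best[0] - 1e-12:
            best = (ssr, tau, coef, X)
    _, tau_star, coef, X = best
    resid = y - X @ coef
    rms = np.sqrt(np.mean(resid**2, axis=0))
    return EcmModel(coef[0], coef[1], coef[2], float(tau_star), rms)


def apply_ecm(model: EcmModel, ext: RpmTrace) -> Trace3D:
    """Evaluate the model at every external-trace timestamp.

    ``EXT(t - tau)`` clamps to the earliest sample for the first ``tau``
    seconds, mirroring the generator's edge rule.
    """
    X = _design(ext, ext.t, model.tau_s)
    coef = np.stack([model.A, model.B, model.C], axis=0)  # (3 regressors, 3 dirs)
    return Trace3D(ext.t, X @ coef)


def rms_error(est: Trace3D, truth: Trace3D) -> np.ndarray:
    """Per-direction RMS difference (mm); truth interpolated onto ``est`` times."""
    clean = est.dropna()
    m = (clean.t >= truth.t[0]) & (clean.t <= truth.t[-1])
    if not m.any():
        raise ValueError("no overlapping time support")
    diff = clean.pos[m] - truth.interp(clean.t[m])
    return np.sqrt(np.mean(diff**2, axis=0))


def summarize(model: EcmModel) -> str:
    lines = [f"tau = {model.tau_s:.3f} s"]
    for k, ax in enumerate(AXES):
        lines.append(
            f"{ax.upper()}: A={model.A[k]:+.3f}  B={model.B[k]:+.3f}  "
            f"C={model.C[k]:+.3f} mm  RMS={model.rms_fit_mm[k]:.2f} mm"
        )
    return "\n".join(lines)
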