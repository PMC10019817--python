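"""Core time-series containers shared by every stage of the pipeline.

Patient coordinate convention (fixed throughout the package):

* axis 0 — LR, left-right, +left
* axis 1 — CC, cranio-caudal, +cranial
* axis 2 — AP, anterior-posterior, +anterior

Exhale corresponds to the *maximal* CC coordinate (the liver moves
cranially at exhale) and, for the external surrogate, to the maximal
signal value.  Modules that depend on the exhale sign expose a flip
flag rather than hard-coding the direction twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXES = ("lr", "cc", "ap")
LR, CC, AP = 0, 1, 2

#: default sampling interval of the gating log, seconds
RPM_DT_S = 0.040


@dataclass
class Trace3D:
    """Timestamped rigid-body position in patient coordinates.

    ``pos`` rows may contain NaN to mark gaps (e.g. projections where a
    marker was not detected); infinities are rejected.
    """

    t: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        if self.t.ndim != 1:
            raise ValueError("t must be one-dimensional")
        if self.pos.shape != (self.t.size, 3):
            raise ValueError(
                f"pos must have shape (n, 3); got {self.pos.shape} for n={self.t.size}"
            )
        if self.t.size == 0:
            raise ValueError("empty trace")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite timestamps")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(np.isinf(self.pos)):
            raise ValueError("infinite positions")

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of samples with no NaN component."""
        return np.all(np.isfinite(self.pos), axis=1)

    def dropna(self) -> "Trace3D":
        m = self.valid
        if not m.any():
            raise ValueError("trace has no valid samples")
        return Trace3D(self.t[m], self.pos[m])

    def interp(self, t_new: np.ndarray) -> np.ndarray:
        """Linear interpolation (clamped at the ends), skipping gap samples."""
        clean = self.dropna()
        t_new = np.asarray(t_new, dtype=float)
        out = np.empty((t_new.size, 3))
        for k in range(3):
            out[:, k] = np.interp(t_new, clean.t, clean.pos[:, k])
        return out

    def shifted(self, d: np.ndarray) -> "Trace3D":
        """Trace rigidly translated by the 3-vector ``d`` (mm)."""
        return Trace3D(self.t, self.pos + np.asarray(d, dtype=float))

    def time_shifted(self, dt: float) -> "Trace3D":
        return Trace3D(self.t + dt, self.pos)


@dataclass
class RpmTrace:
    """External 1D respiratory surrogate (marker-block position) with gate bit.

    Sampled on a uniform grid, 40 ms by default, matching the resolution
    of the gating log file.
    """

    t: np.ndarray
    ext: np.ndarray
    gate_on: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ext = np.asarray(self.ext, dtype=float)
        if self.gate_on is None:
            self.gate_on = np.zeros(self.t.size, dtype=bool)
        self.gate_on = np.asarray(self.gate_on, dtype=bool)
        if not (self.t.size == self.ext.size == self.gate_on.size):
            raise ValueError("t, ext and gate_on must have equal length")
        if self.t.size < 2:
            raise ValueError("need at least two samples")
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.allclose(dts, dts[0], rtol=0, atol=1e-9):
            raise ValueError("sampling must be uniform")
        if not np.all(np.isfinite(self.ext)):
            raise ValueError("non-finite signal values")

    @property
    def dt_s(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def interp(self, t_new: np.ndarray) -> np.ndarray:
        """Signal linearly interpolated at ``t_new`` (clamped at the ends)."""
        return np.interp(np.asarray(t_new, dtype=float), self.t, self.ext)

    def with_gate(self, gate_on: np.ndarray) -> "RpmTrace":
        return RpmTrace(self.t, self.ext, gate_on)
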