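"""Synthetic respiratory motion with a known external-internal coupling.

The generator produces the *external* surrogate signal first and derives
the internal tumor motion from it through a ground-truth instance of the
augmented linear correlation model

    INT_d(t) = A_d * EXT(t) + B_d * EXT(t - tau) + C_d,   d in {LR, CC, AP}

so that the downstream model fit has an exactly recoverable truth.

The breathing waveform within one cycle is

    ext(t) = baseline - a_i * sin^(2n)(pi * t_loc / T_i)

which equals the baseline (exhale) at both cycle boundaries and dips to
``baseline - a_i`` at mid-cycle (inhale).  For n >= 1 the signal dwells
near exhale, reproducing the extended time real breathing spends near
the exhale phase.  Cycle period and amplitude are jittered per cycle;
a slow baseline drift and white observation noise can be added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import CC, RPM_DT_S, RpmTrace, Trace3D

__all__ = [
    "BreathingParams",
    "GroundTruthEcm",
    "generate_external_trace",
    "apply_ground_truth_ecm",
    "place_markers",
]


@dataclass
class BreathingParams:
    """Parameters of the quasi-periodic breathing generator.

    Amplitudes are peak-to-trough, per direction (LR, CC, AP).  The
    defaults describe typical free-breathing liver motion: total
    excursions of 2-3 cm dominated by the CC direction, a ~4 s period
    with ~10% cycle-to-cycle variability, and a slow cranial baseline
    drift over a treatment session.
    """

    period_s: float = 4.0
    period_sd: float = 0.3
    amp_mm: tuple[float, float, float] = (3.0, 20.0, 10.0)
    amp_sd_frac: float = 0.1
    exhale_shape_n: int = 2
    drift_mm_per_min: tuple[float, float, float] = (0.0, 0.10, -0.05)
    noise_sd_mm: float = 0.0
    seed: int = 0
    #: which amplitude/drift component drives the external surrogate
    surrogate_axis: int = CC
    #: flip so that exhale is the signal minimum instead of the maximum
    exhale_is_max: bool = True

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if any(a < 0 for a in self.amp_mm):
            raise ValueError("amp_mm components must be non-negative")
        if self.exhale_shape_n < 1:
            raise ValueError("exhale_shape_n must be >= 1")


@dataclass
class GroundTruthEcm:
    """Known coefficients of the external-internal coupling used by the
    generator; per-direction gains A, B (mm/mm), offsets C (mm) and a
    shared delay tau (s)."""

    A: tuple[float, float, float] = (0.15, 1.00, 0.50)
    B: tuple[float, float, float] = (0.00, 0.25, 0.10)
    C: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tau_s: float = 0.20

    def __post_init__(self) -> None:
        if self.tau_s < 0:
            raise ValueError("tau_s must be non-negative")
        for name in ("A", "B", "C"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")


def _cycle_table(params: BreathingParams, duration_s: float, rng: np.random.Generator):
    """Cycle start times, periods and amplitude factors covering the trace."""
    starts, periods, amps = [0.0], [], []
    t = 0.0
    while t <= duration_s:
        T = max(0.5, rng.normal(params.period_s, params.period_sd))
        a = max(0.0, rng.normal(1.0, params.amp_sd_frac))
        periods.append(T)
        amps.append(a)
        t += T
        starts.append(t)
    return np.asarray(starts), np.asarray(periods), np.asarray(amps)


def generate_external_trace(
    params: BreathingParams,
    duration_s: float,
    dt_s: float = RPM_DT_S,
    baseline_mm: float = 0.0,
) -> RpmTrace:
    """Simulate the external surrogate recording (RPM-like block position).

    Deterministic for a fixed ``params.seed``.  The gate bit is left all
    False; gating is applied by the delivery simulator.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    rng = np.random.default_rng(params.seed)
    starts, periods, amp_fracs = _cycle_table(params, duration_s, rng)

    t = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, periods.size - 1)
    t_loc = t - starts[idx]
    amp = params.amp_mm[params.surrogate_axis] * amp_fracs[idx]
    phase = np.pi * t_loc / periods[idx]
    wave = np.sin(phase) ** (2 * params.exhale_shape_n)
    sgn = 1.0 if params.exhale_is_max else -1.0
    drift = params.drift_mm_per_min[params.surrogate_axis] * t / 60.0
    ext = baseline_mm - sgn * amp * wave + sgn * drift
    if params.noise_sd_mm > 0:
        ext = ext + rng.normal(0.0, params.noise_sd_mm, size=ext.shape)
    return RpmTrace(t, ext)


def apply_ground_truth_ecm(
    ext: RpmTrace,
    gt: GroundTruthEcm,
    noise_sd_mm: float = 0.0,
    seed: int | None = None,
) -> Trace3D:
    """Derive the internal tumor trajectory from the external signal.

    ``EXT(t - tau)`` is obtained by linear interpolation of the external
    trace; times before ``tau`` clamp to the earliest available sample
    (affects less than one breathing cycle at the start).
    """
    if gt.tau_s >= ext.duration_s:
        raise ValueError(
            f"tau_s={gt.tau_s} must be smaller than the trace duration {ext.duration_s}"
        )
    e_now = ext.ext
    e_lag = ext.interp(ext.t - gt.tau_s)
    A = np.asarray(gt.A)
    B = np.asarray(gt.B)
    C = np.asarray(gt.C)
    pos = e_now[:, None] * A[None, :] + e_lag[:, None] * B[None, :] + C[None, :]
    if noise_sd_mm > 0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.normal(0.0, noise_sd_mm, size=pos.shape)
    return Trace3D(ext.t, pos)


def place_markers(
    centroid: Trace3D, offsets: list | np.ndarray
) -> tuple[list[Trace3D], Trace3D]:
    """Rigidly attach fiducial markers at fixed offsets around a moving centroid.

    Returns the per-marker traces and their exact centroid trace (the
    input motion translated by the mean offset).  With offsets summing
    to zero the returned centroid equals the input trace.
    """
    offsets = np.asarray(offsets, dtype=float)
    if offsets.ndim == 1:
        offsets = offsets[None, :]
    if offsets.size == 0:
        raise ValueError("need at least one marker offset")
    if offsets.shape[1] != 3:
        raise ValueError("offsets must be 3-vectors")
    markers = [Trace3D(centroid.t, centroid.pos + off[None, :]) for off in offsets]
    centroid_of_markers = Trace3D(centroid.t, centroid.pos + offsets.mean(axis=0))
    return markers, centroid_of_markers
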