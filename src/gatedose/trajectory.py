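"""Probability-based 3D trajectory estimation from 2D cone-beam projections.

A single 2D projection resolves a marker's position only up to the ray
from the x-ray source through the detected panel point.  The method
fits a 3D Gaussian probability density of the marker position by
maximum likelihood over all projections — for each projection the
likelihood of the observation is the 3D density marginalized along the
ray direction, a 2D Gaussian in the ray-transverse coordinates — and
then resolves the unseen along-ray coordinate of every projection as
the conditional mean of the fitted Gaussian restricted to that ray.
The conditional mean lies exactly on the ray, so each 3D estimate
reprojects onto its observed panel position.

Only Gaussian position densities are supported; the conditional mean
along a ray is then available in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .cbct import ProjectionSet, ScannerGeometry
from .traces import Trace3D

__all__ = [
    "GaussianPdf3D",
    "backproject_ray",
    "fit_position_pdf",
    "estimate_3d_trajectory",
    "centroid_trajectory",
]

_MIN_ARC_DEG = 90.0
_MIN_PROJ = 6


@dataclass
class GaussianPdf3D:
    """3D Gaussian marker-position density (mean mm, covariance mm^2)."""

    mean: np.ndarray
    cov: np.ndarray
    narrow_arc: bool = False
    nll_history: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (3,) or self.cov.shape != (3, 3):
            raise ValueError("mean must be a 3-vector and cov a 3x3 matrix")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.cov))):
            raise ValueError("non-finite parameters")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.cov)) < -1e-8:
            raise ValueError("covariance must be positive semi-definite")


def backproject_ray(geom: ScannerGeometry, angle_deg: float, uv_mm) -> tuple[np.ndarray, np.ndarray]:
    """Ray from the source through a detected panel point, in patient coords.

    Returns ``(origin, direction)`` with unit ``direction`` pointing from
    the source towards the panel.
    """
    u, v = np.asarray(uv_mm, dtype=float)
    source, u_hat, v_hat, beam = geom.axes(angle_deg)
    panel_pt = source + geom.sid_mm * beam + u * u_hat + v * v_hat
    d = panel_pt - source
    return source, d / np.linalg.norm(d)


def _rays(proj: ProjectionSet, geom: ScannerGeometry, marker: int = 0):
    """Detected-projection rays: origins (n,3), unit dirs (n,3), indices."""
    idx = np.flatnonzero(proj.detected[:, marker])
    origins = np.empty((idx.size, 3))
    dirs = np.empty((idx.size, 3))
    for k, i in enumerate(idx):
        o, d = backproject_ray(geom, proj.angle_deg[i], proj.uv_mm[i, marker])
        origins[k] = o
        dirs[k] = d
    return origins, dirs, idx


def _transverse_basis(dirs: np.ndarray) -> np.ndarray:
    """Per-ray orthonormal basis of the plane perpendicular to the ray, (n,3,2)."""
    n = dirs.shape[0]
    ref = np.tile(np.array([0.0, 1.0, 0.0]), (n, 1))
    nearly_parallel = np.abs(dirs[:, 1]) > 0.9
    ref[nearly_parallel] = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(dirs, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(dirs, e1)
    return np.stack([e1, e2], axis=2)


def _ls_ray_intersection(origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Point minimizing the summed squared distance to all rays."""
    eye = np.eye(3)
    P = eye[None, :, :] - dirs[:, :, None] * dirs[:, None, :]
    A = P.sum(axis=0)
    b = np.einsum("nij,nj->i", P, origins)
    return np.linalg.solve(A, b)


def _nll(mu: np.ndarray, Sigma: np.ndarray, E: np.ndarray, z: np.ndarray) -> float:
    """Negative log-likelihood of ray-transverse observations under N(mu, Sigma)."""
    S = np.einsum("nia,ij,njb->nab", E, Sigma, E)
    det = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] ** 2
    if np.any(det <= 0) or not np.all(np.isfinite(det)):
        return np.inf
    r = z - np.einsum("nia,i->na", E, mu)
    quad = (
        S[:, 1, 1] * r[:, 0] ** 2
        - 2.0 * S[:, 0, 1] * r[:, 0] * r[:, 1]
        + S[:, 0, 0] * r[:, 1] ** 2
    ) / det
    return float(0.5 * np.sum(np.log(det) + quad))


def _unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = theta[:3]
    L = np.zeros((3, 3))
    L[np.diag_indices(3)] = np.exp(np.clip(theta[3:6], -20.0, 20.0))
    L[1, 0], L[2, 0], L[2, 1] = theta[6:9]
    return mu, L @ L.T


def fit_position_pdf(
    proj: ProjectionSet,
    geom: ScannerGeometry,
    marker: int = 0,
    n_starts: int = 3,
    seed: int = 0,
) -> GaussianPdf3D:
    """Maximum-likelihood 3D Gaussian position density from 2D projections.

    The covariance is parameterized by its Cholesky factor (log-scaled
    diagonal) and the likelihood is maximized with L-BFGS-B from
    ``n_starts`` starting points to hedge against local maxima.
    """
    origins, dirs, idx = _rays(proj, geom, marker)
    if idx.size < _MIN_PROJ:
        raise ValueError(f"need at least {_MIN_PROJ} detected projections, got {idx.size}")
    narrow = proj.arc_span_deg(marker) < _MIN_ARC_DEG
    if narrow:
        warnings.warn(
            "detected projections span less than 90 deg of arc; "
            "the along-ray component is poorly constrained",
            stacklevel=2,
        )
    E = _transverse_basis(dirs)
    z = np.einsum("nia,ni->na", E, origins)

    mu0 = _ls_ray_intersection(origins, dirs)
    r0 = z - np.einsum("nia,i->na", E, mu0)
    s0 = max(float(np.sqrt(np.mean(r0**2))), 0.05)

    rng = np.random.default_rng(seed)
    history: list[float] = []
    best = None
    for s in range(max(1, n_starts)):
        if s == 0:
            theta0 = np.concatenate([mu0, np.log([s0, s0, s0]), np.zeros(3)])
        else:
            jitter_mu = rng.normal(0.0, s0, size=3)
            jitter_ls = rng.normal(0.0, 0.7, size=3)
            theta0 = np.concatenate(
                [mu0 + jitter_mu, np.log(s0) + jitter_ls, np.zeros(3)]
            )

        def fun(theta: np.ndarray) -> float:
            mu, Sigma = _unpack(theta)
            return _nll(mu, Sigma, E, z)

        res = minimize(
            fun,
            theta0,
            method="L-BFGS-B",
            callback=lambda xk: history.append(fun(xk)),
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, Sigma = _unpack(best.x)
    return GaussianPdf3D(mu, Sigma, narrow_arc=narrow, nll_history=np.asarray(history))


def _condition_on_ray(
    pdf: GaussianPdf3D, origin: np.ndarray, direction: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Mean of the Gaussian restricted to a ray (closed form).

    Along the ray ``p(s) = o + s d`` the restricted density is Gaussian in
    ``s`` with mean ``s* = d' Sigma^-1 (mu - o) / (d' Sigma^-1 d)``.  If the
    density is singular along the ray the nearest ray point to the mean
    is returned with a flag.
    """
    cov = pdf.cov + 1e-12 * np.eye(3)
    try:
        w = np.linalg.solve(cov, direction)
        denom = float(direction @ w)
        if denom <= 1e-12 or not np.isfinite(denom):
            raise np.linalg.LinAlgError
        s = float((pdf.mean - origin) @ w) / denom
        return origin + s * direction, False
    except np.linalg.LinAlgError:
        s = float(direction @ (pdf.mean - origin))
        return origin + s * direction, True


def estimate_3d_trajectory(
    proj: ProjectionSet,
    geom: ScannerGeometry,
    pdf: GaussianPdf3D,
    marker: int = 0,
) -> Trace3D:
    """Resolve each projection's 3D marker position as the conditional mean
    of the fitted Gaussian on the backprojected ray.

    Undetected projections yield NaN gap samples; timestamps are copied
    from the projection set.
    """
    origins, dirs, idx = _rays(proj, geom, marker)
    pos = np.full((proj.t.size, 3), np.nan)
    for k, i in enumerate(idx):
        est, _flagged = _condition_on_ray(pdf, origins[k], dirs[k])
        pos[i] = est
    return Trace3D(proj.t, pos)


def centroid_trajectory(per_marker: list[Trace3D], require_all: bool = False) -> Trace3D:
    """Per-timestamp mean over the markers detected at that timestamp.

    All traces must share timestamps; a timestamp with no detected
    marker remains a gap.  With ``require_all`` a timestamp where *any*
    marker is missing becomes a gap — recommended when markers sit at
    large offsets from the group centroid, where a partial mean is
    biased by half the missing marker's offset.
    """
    if not per_marker:
        raise ValueError("need at least one marker trace")
    t = per_marker[0].t
    for tr in per_marker[1:]:
        if tr.t.shape != t.shape or not np.allclose(tr.t, t, atol=1e-9):
            raise ValueError("marker traces must share timestamps")
    stack = np.stack([tr.pos for tr in per_marker], axis=0)  # (m, n, 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    if require_all:
        partial = np.any(np.isnan(stack), axis=(0, 2))
        mean[partial] = np.nan
    return Trace3D(t, mean)
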