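"""Analytic pencil-beam dose engine, toy SFUD-like planning and
motion-including spot-shift dose reconstruction.

The engine computes dose on a uniform water phantom as a sum of spot
contributions

    dose(p) = MU * D(z(p); E) * G(r(p); sigma(E, z))

where ``z`` is the water depth of voxel ``p`` along the field's beam
axis, ``D`` is an analytic Bragg curve normalized to unit peak at the
proton range, and ``G`` is a normalized 2D lateral Gaussian around the
spot's beam's-eye-view (BEV) position.  The range-energy relation is
the Bragg-Kleeman power law R = alpha * E^p in water.

Tumor motion is encoded into a plan by shifting every spot *opposite*
to the lateral (BEV) component of the tumor displacement at its
delivery time, and converting the in-depth component (along the beam,
positive away from the source) into an energy change such that the new
range equals the old range plus the in-depth displacement.  Computing
the motion-encoded plan on the static phantom yields the
motion-including reconstructed fraction dose.  All dosimetric
comparisons are relative (planned vs reconstructed with the same
engine); the engine makes no absolute clinical dose claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "range_from_energy",
    "energy_from_range",
    "Phantom",
    "DoseGrid",
    "DvhMetrics",
    "SpotPlan",
    "FieldGeometry",
    "bragg_curve",
    "lateral_sigma_mm",
    "spot_dose",
    "compute_dose",
    "make_toy_plan",
    "encode_motion",
    "reconstruct_fraction_dose",
    "dvh_metrics",
    "hi_percent",
    "average_fraction_doses",
]

# Bragg-Kleeman range-energy relation in water: R [cm] = ALPHA_CM * E^P_EXP
ALPHA_CM = 0.0022
P_EXP = 1.77

ENERGY_MIN_MEV = 1.0
ENERGY_MAX_MEV = 250.0

#: default machine energy limits (clinical liver beam range)
MACHINE_E_MIN = 71.0
MACHINE_E_MAX = 153.0


def range_from_energy(e_mev) -> np.ndarray | float:
    """Proton range in water (mm) from beam energy (MeV)."""
    e = np.asarray(e_mev, dtype=float)
    if np.any(e < ENERGY_MIN_MEV) or np.any(e > ENERGY_MAX_MEV):
        raise ValueError(f"energy outside [{ENERGY_MIN_MEV}, {ENERGY_MAX_MEV}] MeV")
    r = 10.0 * ALPHA_CM * e**P_EXP
    return float(r) if np.isscalar(e_mev) else r


def energy_from_range(range_mm) -> np.ndarray | float:
    """Inverse of :func:`range_from_energy` (closed form)."""
    r = np.asarray(range_mm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("range must be positive")
    e = (r / (10.0 * ALPHA_CM)) ** (1.0 / P_EXP)
    if np.any(e < ENERGY_MIN_MEV) or np.any(e > ENERGY_MAX_MEV):
        raise ValueError("range corresponds to an energy outside the model domain")
    return float(e) if np.isscalar(range_mm) else e


@dataclass
class Phantom:
    """Uniform water box with a spherical CTV inside an ellipsoidal liver."""

    origin_mm: tuple[float, float, float] = (-60.0, -60.0, -60.0)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    dims: tuple[int, int, int] = (48, 48, 48)
    ctv_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ctv_radius_mm: float = 12.0
    liver_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    liver_semiaxes_mm: tuple[float, float, float] = (45.0, 40.0, 45.0)

    def __post_init__(self) -> None:
        if min(self.spacing_mm) <= 0:
            raise ValueError("spacing must be positive")
        if self.ctv_radius_mm <= 0:
            raise ValueError("CTV radius must be positive")
        c = np.asarray(self.ctv_center_mm) - np.asarray(self.liver_center_mm)
        a = np.asarray(self.liver_semiaxes_mm)
        if np.sum(((np.abs(c) + self.ctv_radius_mm) / a) ** 2) > 3.0:
            raise ValueError("CTV must lie inside the liver")
        lo = np.asarray(self.origin_mm)
        hi = lo + np.asarray(self.spacing_mm) * np.asarray(self.dims)
        lc = np.asarray(self.liver_center_mm)
        if np.any(lc - a < lo) or np.any(lc + a > hi):
            raise ValueError("liver must lie inside the grid")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) voxel-center coordinates (mm), C-order flattening."""
        ax = [
            self.origin_mm[k] + self.spacing_mm[k] * (np.arange(self.dims[k]) + 0.5)
            for k in range(3)
        ]
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([v.ravel() for v in g], axis=1)

    def ctv_mask(self) -> np.ndarray:
        p = self.voxel_centers()
        d2 = np.sum((p - np.asarray(self.ctv_center_mm)) ** 2, axis=1)
        return (d2 <= self.ctv_radius_mm**2).reshape(self.dims)

    def liver_mask(self) -> np.ndarray:
        p = self.voxel_centers()
        q = (p - np.asarray(self.liver_center_mm)) / np.asarray(self.liver_semiaxes_mm)
        return (np.sum(q**2, axis=1) <= 1.0).reshape(self.dims)


@dataclass
class DoseGrid:
    """Voxel dose (Gy) on a phantom grid."""

    values: np.ndarray
    phantom: Phantom

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.phantom.dims):
            raise ValueError("dose array does not match the phantom grid")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("dose must be finite and non-negative")

    def same_grid(self, other: "DoseGrid") -> bool:
        a, b = self.phantom, other.phantom
        return (
            a.dims == b.dims
            and a.origin_mm == b.origin_mm
            and a.spacing_mm == b.spacing_mm
        )


@dataclass
class DvhMetrics:
    """Near-minimum / median / near-maximum dose and homogeneity index."""

    d98_gy: float
    d50_gy: float
    d2_gy: float
    hi_pct: float
    mean_gy: float

    def __post_init__(self) -> None:
        if not self.d98_gy <= self.d50_gy + 1e-9 or not self.d50_gy <= self.d2_gy + 1e-9:
            raise ValueError("require D98 <= D50 <= D2")

    def to_dict(self) -> dict:
        return {
            "D98_gy": self.d98_gy,
            "D50_gy": self.d50_gy,
            "D2_gy": self.d2_gy,
            "HI_pct": self.hi_pct,
            "mean_gy": self.mean_gy,
        }


@dataclass
class SpotPlan:
    """Flat per-spot list of a multi-field PBS plan.

    Spots are ordered field-major with energy layers sorted from the
    highest (deepest) to the lowest energy within each field, matching
    delivery order.
    """

    field: np.ndarray      # field index per spot
    layer: np.ndarray      # energy-layer index within the field
    energy_mev: np.ndarray
    x_bev: np.ndarray      # lateral BEV position u (mm)
    y_bev: np.ndarray      # lateral BEV position v (mm)
    mu: np.ndarray
    gantry_angles_deg: np.ndarray  # one entry per field
    e_min_mev: float = MACHINE_E_MIN
    e_max_mev: float = MACHINE_E_MAX
    prescription_gy: float = 58.0
    n_fractions: int = 15
    n_energy_clipped: int = 0

    def __post_init__(self) -> None:
        arrays = ["field", "layer", "energy_mev", "x_bev", "y_bev", "mu"]
        n = None
        for name in arrays:
            v = np.asarray(getattr(self, name))
            setattr(self, name, v)
            n = v.size if n is None else n
            if v.size != n:
                raise ValueError("per-spot arrays must have equal length")
        self.gantry_angles_deg = np.asarray(self.gantry_angles_deg, dtype=float)
        if np.any(self.mu <= 0):
            raise ValueError("MU must be positive")
        for f in np.unique(self.field):
            sel = self.field == f
            lay = self.layer[sel]
            en = self.energy_mev[sel]
            # within a field, layers are delivered in order of decreasing energy
            layer_e = {}
            for li, ei in zip(lay, en):
                layer_e.setdefault(li, ei)
            es = [layer_e[li] for li in sorted(layer_e)]
            if np.any(np.diff(es) > 1e-9):
                raise ValueError("layers must be sorted descending in energy")

    @property
    def n_spots(self) -> int:
        return self.field.size

    def spots_per_field(self) -> dict[int, int]:
        f, c = np.unique(self.field, return_counts=True)
        return dict(zip(f.tolist(), c.tolist()))


@dataclass
class FieldGeometry:
    """Cached per-voxel BEV coordinates for one field on a phantom.

    The gantry rotates about the CC axis with the same convention as the
    imaging model: at angle 0 the beam travels in the -AP direction.
    ``depth`` is the water depth from the beam-facing face of the grid,
    ``u``/``v`` the lateral BEV coordinates of each voxel.
    """

    angle_deg: float
    beam: np.ndarray
    u_hat: np.ndarray
    v_hat: np.ndarray
    depth: np.ndarray = field(repr=False)
    u: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)

    @classmethod
    def for_phantom(cls, phantom: Phantom, angle_deg: float) -> "FieldGeometry":
        th = np.deg2rad(angle_deg)
        e = np.array([np.sin(th), 0.0, np.cos(th)])  # iso -> source
        beam = -e
        u_hat = np.array([np.cos(th), 0.0, -np.sin(th)])
        v_hat = np.array([0.0, 1.0, 0.0])
        p = phantom.voxel_centers()
        along = p @ beam
        depth = along - along.min()
        return cls(angle_deg, beam, u_hat, v_hat, depth, p @ u_hat, p @ v_hat)


def lateral_sigma_mm(e_mev, depth_mm=0.0):
    """Lateral spot sigma: in-air sigma linear in energy (6 mm at 71 MeV
    to 4 mm at 153 MeV) with small in-depth broadening added in
    quadrature."""
    e = np.asarray(e_mev, dtype=float)
    sigma_air = 6.0 - 2.0 * (e - MACHINE_E_MIN) / (MACHINE_E_MAX - MACHINE_E_MIN)
    sigma_air = np.clip(sigma_air, 1.0, None)
    return np.sqrt(sigma_air**2 + (0.01 * np.asarray(depth_mm)) ** 2)


def _bragg_sigma_mm(r_mm: float) -> float:
    # peak width grows with range; widened vs pure straggling so that
    # layer stacks at the default layer spacing produce a smooth SOBP
    return 1.0 + 0.035 * r_mm


def _bragg_raw(z_mm: np.ndarray, r_mm: float) -> np.ndarray:
    s = _bragg_sigma_mm(r_mm)
    peak = np.exp(-((z_mm - r_mm) ** 2) / (2.0 * s**2))
    plateau = 1.0 / (1.0 + np.exp((z_mm - r_mm) / (s / 1.5)))
    return 0.72 * peak + 0.28 * plateau


def bragg_curve(z_mm, e_mev: float) -> np.ndarray:
    """Analytic depth-dose curve, normalized to unit peak.

    The peak sits at :func:`range_from_energy`, with a Gaussian peak, a
    sigmoid entrance plateau (~30% of peak) and a Gaussian distal
    falloff whose width grows with range.
    """
    r = range_from_energy(e_mev)
    zf = np.linspace(max(0.0, r - 6 * _bragg_sigma_mm(r)), r + 3 * _bragg_sigma_mm(r), 400)
    norm = _bragg_raw(zf, r).max()
    return _bragg_raw(np.asarray(z_mm, dtype=float), r) / norm


def spot_dose(
    energy_mev: float,
    x_bev: float,
    y_bev: float,
    mu: float,
    phantom: Phantom,
    fg: FieldGeometry,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Dose contribution (flat, n_voxels) of one spot; accumulates into ``out``."""
    if out is None:
        out = np.zeros(phantom.n_voxels)
    sig = float(np.atleast_1d(lateral_sigma_mm(energy_mev, range_from_energy(energy_mev)))[0])
    half = 4.5 * sig
    idx = np.flatnonzero(
        (np.abs(fg.u - x_bev) < half) & (np.abs(fg.v - y_bev) < half)
    )
    if idx.size == 0:
        return out
    r2 = (fg.u[idx] - x_bev) ** 2 + (fg.v[idx] - y_bev) ** 2
    lat = np.exp(-r2 / (2.0 * sig**2)) / (2.0 * np.pi * sig**2)
    out[idx] += mu * bragg_curve(fg.depth[idx], energy_mev) * lat
    return out


def compute_dose(plan: SpotPlan, phantom: Phantom) -> DoseGrid:
    """Total plan dose on the phantom (sum of analytic spot contributions)."""
    flat = np.zeros(phantom.n_voxels)
    for fi, angle in enumerate(plan.gantry_angles_deg):
        sel = np.flatnonzero(plan.field == fi)
        if sel.size == 0:
            continue
        fg = FieldGeometry.for_phantom(phantom, angle)
        for k in sel:
            spot_dose(
                float(plan.energy_mev[k]),
                float(plan.x_bev[k]),
                float(plan.y_bev[k]),
                float(plan.mu[k]),
                phantom,
                fg,
                out=flat,
            )
    return DoseGrid(flat.reshape(phantom.dims), phantom)


def make_toy_plan(
    phantom: Phantom,
    gantry_angles_deg=(0.0, 120.0, 240.0),
    layer_spacing_mm: float = 5.0,
    spot_spacing_mm: float = 5.0,
    prescription_gy: float = 58.0,
    n_fractions: int = 15,
    margin_mm: float = 6.0,
    max_spots_per_field: int = 2134,
    seed: int = 0,
) -> SpotPlan:
    """Build a single-field-uniform-dose-like plan covering the CTV.

    Each field gets energy layers spanning the CTV depth extent and a
    rectangular spot grid covering the CTV cross-section plus a margin
    at every layer.  Spot MUs are set per field by non-negative least
    squares so that each field alone delivers a uniform share of the
    per-fraction prescription to the CTV.
    """
    if phantom.ctv_radius_mm <= 0:
        raise ValueError("zero-radius CTV")
    gantry_angles_deg = np.asarray(gantry_angles_deg, dtype=float)
    n_fields = gantry_angles_deg.size
    ctv = phantom.ctv_mask().ravel()
    ctv_idx = np.flatnonzero(ctv)
    rng = np.random.default_rng(seed)

    fields, layers, energies, xs, ys = [], [], [], [], []
    for fi, angle in enumerate(gantry_angles_deg):
        fg = FieldGeometry.for_phantom(phantom, angle)
        d_ctv = fg.depth[ctv_idx]
        d_lo, d_hi = d_ctv.min(), d_ctv.max()
        n_layers = int(np.ceil((d_hi - d_lo) / layer_spacing_mm)) + 1
        depths = d_hi - layer_spacing_mm * np.arange(n_layers)  # deepest first
        c_u = float(np.mean(fg.u[ctv_idx]))
        c_v = float(np.mean(fg.v[ctv_idx]))
        r_half = phantom.ctv_radius_mm + margin_mm
        n_side = int(np.floor(r_half / spot_spacing_mm))
        g = spot_spacing_mm * np.arange(-n_side, n_side + 1)
        count = 0
        for li, dep in enumerate(depths):
            energy = energy_from_range(dep)
            # lateral extent of the CTV at this layer depth, plus margin
            dz = abs(dep - 0.5 * (d_lo + d_hi))
            r_layer = np.sqrt(max(phantom.ctv_radius_mm**2 - min(dz, phantom.ctv_radius_mm) ** 2, 0.0))
            r_keep = r_layer + margin_mm
            for gu in g:
                for gv in g:
                    if np.hypot(gu, gv) > r_keep:
                        continue
                    fields.append(fi)
                    layers.append(li)
                    energies.append(energy)
                    xs.append(c_u + gu)
                    ys.append(c_v + gv)
                    count += 1
        if count == 0:
            raise ValueError(f"field {fi}: no spots cover the CTV")
        if count > max_spots_per_field:
            raise ValueError(
                f"field {fi}: {count} spots exceed the cap of {max_spots_per_field}; "
                "increase spot or layer spacing"
            )

    fields = np.asarray(fields)
    layers = np.asarray(layers)
    energies = np.asarray(energies, dtype=float)
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if np.any(energies < MACHINE_E_MIN) or np.any(energies > MACHINE_E_MAX):
        raise ValueError("required layer energies fall outside the machine limits")

    # MU optimization: each field alone -> uniform share of the fraction dose
    sample_idx = ctv_idx
    if sample_idx.size > 1500:
        sample_idx = rng.choice(sample_idx, size=1500, replace=False)
    target = prescription_gy / n_fractions / n_fields
    mus = np.ones(fields.size)
    for fi, angle in enumerate(gantry_angles_deg):
        sel = np.flatnonzero(fields == fi)
        fg = FieldGeometry.for_phantom(phantom, angle)
        A = np.empty((sample_idx.size, sel.size))
        for j, k in enumerate(sel):
            sig = float(np.atleast_1d(lateral_sigma_mm(energies[k], range_from_energy(energies[k])))[0])
            r2 = (fg.u[sample_idx] - xs[k]) ** 2 + (fg.v[sample_idx] - ys[k]) ** 2
            lat = np.exp(-r2 / (2.0 * sig**2)) / (2.0 * np.pi * sig**2)
            A[:, j] = bragg_curve(fg.depth[sample_idx], energies[k]) * lat
        w, _ = nnls(A, np.full(sample_idx.size, target))
        mus[sel] = w

    keep = mus > 1e-9  # drop spots the optimizer switched off
    return SpotPlan(
        field=fields[keep],
        layer=layers[keep],
        energy_mev=energies[keep],
        x_bev=xs[keep],
        y_bev=ys[keep],
        mu=mus[keep],
        gantry_angles_deg=gantry_angles_deg,
        prescription_gy=prescription_gy,
        n_fractions=n_fractions,
    )


def encode_motion(plan: SpotPlan, per_spot_disp: np.ndarray) -> SpotPlan:
    """Encode per-spot tumor displacements into a deliverable plan.

    The displacement (patient coordinates, mm) at each spot's delivery
    time is decomposed per field into the BEV-lateral components and the
    in-depth component along the beam axis (positive away from the
    source).  Spots are shifted by the negative lateral displacement;
    the energy is changed so that the new range equals the old range
    plus the in-depth displacement.  Energies are clipped to the machine
    limits; the number of clipped spots is recorded on the plan.
    """
    disp = np.asarray(per_spot_disp, dtype=float)
    if disp.shape != (plan.n_spots, 3):
        raise ValueError(f"need one 3-vector per spot; got shape {disp.shape}")
    if not np.all(np.isfinite(disp)):
        raise ValueError("displacements must be finite")

    x_new = plan.x_bev.copy()
    y_new = plan.y_bev.copy()
    e_new = plan.energy_mev.copy()
    n_clipped = 0
    for fi, angle in enumerate(plan.gantry_angles_deg):
        sel = np.flatnonzero(plan.field == fi)
        if sel.size == 0:
            continue
        th = np.deg2rad(angle)
        beam = -np.array([np.sin(th), 0.0, np.cos(th)])
        u_hat = np.array([np.cos(th), 0.0, -np.sin(th)])
        v_hat = np.array([0.0, 1.0, 0.0])
        d_u = disp[sel] @ u_hat
        d_v = disp[sel] @ v_hat
        d_depth = disp[sel] @ beam
        x_new[sel] = plan.x_bev[sel] - d_u
        y_new[sel] = plan.y_bev[sel] - d_v
        r_new = range_from_energy(plan.energy_mev[sel]) + d_depth
        e_raw = (np.maximum(r_new, 1e-3) / (10.0 * ALPHA_CM)) ** (1.0 / P_EXP)
        clipped = np.clip(e_raw, plan.e_min_mev, plan.e_max_mev)
        n_clipped += int(np.sum(np.abs(clipped - e_raw) > 1e-9))
        # zero in-depth motion passes the energy through bit-exactly
        e_new[sel] = np.where(d_depth == 0.0, plan.energy_mev[sel], clipped)

    out = replace(plan)
    out.x_bev = x_new
    out.y_bev = y_new
    out.energy_mev = e_new
    out.n_energy_clipped = n_clipped
    return out


def reconstruct_fraction_dose(
    plan: SpotPlan, per_spot_disp: np.ndarray, phantom: Phantom
) -> DoseGrid:
    """Motion-including fraction dose: motion-encoded plan on the static phantom."""
    return compute_dose(encode_motion(plan, per_spot_disp), phantom)


def _dx(doses: np.ndarray, x: float) -> float:
    """Dose received by at least x% of the voxels (linear interpolation)."""
    return float(np.percentile(doses, 100.0 - x))


def hi_percent(d98: float, d50: float, d2: float) -> float:
    """Homogeneity index HI% = (D2 - D98) / D50 * 100."""
    return (d2 - d98) / d50 * 100.0


def dvh_metrics(dose: DoseGrid, mask: np.ndarray) -> DvhMetrics:
    """DVH point metrics over a structure mask."""
    mask = np.asarray(mask, dtype=bool)
    doses = dose.values[mask]
    if doses.size == 0:
        raise ValueError("empty structure mask")
    d98, d50, d2 = _dx(doses, 98.0), _dx(doses, 50.0), _dx(doses, 2.0)
    return DvhMetrics(d98, d50, d2, hi_percent(d98, d50, d2), float(doses.mean()))


def average_fraction_doses(doses: list[DoseGrid]) -> DoseGrid:
    """Voxelwise mean of per-fraction doses on a common grid."""
    if not doses:
        raise ValueError("need at least one dose grid")
    first = doses[0]
    for d in doses[1:]:
        if not first.same_grid(d):
            raise ValueError("dose grids do not match")
    return DoseGrid(np.mean([d.values for d in doses], axis=0), first.phantom)
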