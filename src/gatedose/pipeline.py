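"""End-to-end synthetic treatment-fraction simulation and analysis.

Ties every stage together the way a clinical fraction unfolds:

1. a full-session external surrogate recording and the ground-truth
   internal motion derived from it (known coupling, drift, markers);
2. a setup cone-beam scan, an online registration with a configurable
   human error, and the couch correction;
3. gated spot delivery of a toy SFUD-like plan with machine-log
   emission;
4. a post-treatment cone-beam scan;
5. the retrospective analysis chain: marker trajectory estimation from
   the projections, RPM/CBCT synchronization via the tungsten sphere,
   correlation-model fit, machine-log synchronization, per-spot tumor
   positions, motion-including dose reconstruction and the fraction
   report.

Every random choice derives from a single scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import cbct, delivery, dose, ecm, motion, report, trajectory
from .traces import AP, RpmTrace, Trace3D

__all__ = ["FractionScenario", "FractionResult", "run_fraction"]


@dataclass
class FractionScenario:
    """Configuration of one simulated gated treatment fraction."""

    seed: int = 0
    breathing: motion.BreathingParams | None = None
    gt_ecm: motion.GroundTruthEcm | None = None
    marker_offsets_mm: np.ndarray = dc_field(
        default_factory=lambda: np.array(
            [[12.0, 5.0, -8.0], [-10.0, -9.0, 4.0], [-2.0, 4.0, 4.0]]
        )
    )
    scanner: cbct.ScannerGeometry | None = None
    rates: delivery.DeliveryRates | None = None
    phantom: dose.Phantom | None = None
    n_fields: int = 3
    setup_scan_start_s: float = 5.0
    treatment_gap_s: float = 30.0  # setup end -> beam start (couch correction etc.)
    post_gap_s: float = 15.0       # delivery end -> post-treatment scan
    online_match_error_mm: tuple[float, float, float] = (0.4, 0.8, -0.4)
    cbct_clock_offset_s: float = 7.5   # CBCT clock behind the gating log
    machine_clock_offset_s: float = 13.37
    noise_sd_px: float = 0.5
    detect_prob: float = 0.98
    trajectory_n_starts: int = 1
    duty_target: float = 0.5

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        if self.breathing is None:
            self.breathing = motion.BreathingParams(seed=int(rng.integers(2**31)))
        if self.gt_ecm is None:
            self.gt_ecm = motion.GroundTruthEcm()
        if self.scanner is None:
            self.scanner = cbct.ScannerGeometry(n_proj=300, scan_duration_s=60.0)
        if self.rates is None:
            self.rates = delivery.DeliveryRates()
        if self.phantom is None:
            self.phantom = dose.Phantom()


@dataclass
class FractionResult:
    """Artifacts of one simulated and analyzed fraction."""

    rpm: RpmTrace
    truth_tumor: Trace3D
    est_tumor_post: Trace3D
    ecm_model: ecm.EcmModel
    gating: delivery.GatingConfig
    timeline: delivery.DeliveryTimeline
    recovered_offset_s: float
    recovered_scale: float
    rpm_cbct_offset_s: float
    per_spot_positions_mm: np.ndarray
    plan: dose.SpotPlan
    dose_planned: dose.DoseGrid
    dose_reconstructed: dose.DoseGrid
    fraction_report: report.FractionReport


def _sphere_trace(rpm_like: RpmTrace) -> Trace3D:
    """Tungsten sphere rides on the RPM block: AP follows the surrogate."""
    pos = np.zeros((rpm_like.t.size, 3))
    pos[:, AP] = rpm_like.ext
    return Trace3D(rpm_like.t, pos)


def run_fraction(sc: FractionScenario) -> FractionResult:
    rng = np.random.default_rng(sc.seed + 1)
    scan_dur = sc.scanner.scan_duration_s

    # ---- plan (per-fraction prescription) --------------------------------
    angles = np.linspace(0.0, 360.0, sc.n_fields, endpoint=False)
    plan = dose.make_toy_plan(sc.phantom, gantry_angles_deg=angles, seed=sc.seed)

    # ---- session-long surrogate + ground-truth internal motion ----------
    # session length: setup scan + gap + delivery + gap + post scan; the
    # delivery duration is not known in advance, so simulate generously
    # and trim afterwards.
    est_beam_on = plan.mu.sum() / sc.rates.mu_per_s
    session_s = (
        sc.setup_scan_start_s
        + scan_dur
        + sc.treatment_gap_s
        + 4.0 * est_beam_on
        + 60.0 * plan.layer.max()
        + sc.post_gap_s
        + scan_dur
        + 120.0
    )
    rpm = motion.generate_external_trace(sc.breathing, session_s)
    truth = motion.apply_ground_truth_ecm(rpm, sc.gt_ecm)
    markers, truth_centroid = motion.place_markers(
        truth, sc.marker_offsets_mm - sc.marker_offsets_mm.mean(axis=0)
    )
    sphere = _sphere_trace(rpm)

    # ---- gating-window calibration on the pre-treatment recording -------
    n_pre = int((sc.setup_scan_start_s + scan_dur) / rpm.dt_s)
    pre = RpmTrace(rpm.t[:n_pre], rpm.ext[:n_pre])
    gating_cfg = delivery.calibrate_gating_window(pre, duty_target=sc.duty_target)
    rpm = delivery.apply_gating(rpm, gating_cfg)

    # ---- setup CBCT, online registration, couch correction --------------
    def scan(t0: float) -> cbct.ProjectionSet:
        proj = cbct.simulate_cbct(
            sc.scanner,
            markers + [sphere],
            t0_s=t0,
            noise_sd_px=sc.noise_sd_px,
            detect_prob=sc.detect_prob,
            seed=int(rng.integers(2**31)),
        )
        # the CBCT runs on its own clock, behind the gating log
        proj.t = proj.t - sc.cbct_clock_offset_s
        return proj

    def analyze_scan(proj: cbct.ProjectionSet):
        per_marker = []
        for j in range(len(markers)):
            pdf = trajectory.fit_position_pdf(
                proj, sc.scanner, marker=j, n_starts=sc.trajectory_n_starts, seed=sc.seed
            )
            per_marker.append(trajectory.estimate_3d_trajectory(proj, sc.scanner, pdf, marker=j))
        centroid = trajectory.centroid_trajectory(per_marker, require_all=True)
        j_sph = len(markers)
        pdf_s = trajectory.fit_position_pdf(
            proj, sc.scanner, marker=j_sph, n_starts=sc.trajectory_n_starts, seed=sc.seed
        )
        sph = trajectory.estimate_3d_trajectory(proj, sc.scanner, pdf_s, marker=j_sph)
        offset = delivery.synchronize_rpm_cbct(rpm, sph, search_s=30.0)
        return centroid.time_shifted(offset), sph, offset

    proj_setup = scan(sc.setup_scan_start_s)
    est_setup, _, _ = analyze_scan(proj_setup)

    # trajectory-based setup: exhale position of the estimated setup trace
    traj_setup = report.exhale_position(est_setup)
    online_match = traj_setup + np.asarray(sc.online_match_error_mm)
    reg_err = report.online_registration_error(traj_setup, online_match)
    # the couch correction shifts the patient by -online_match; from here on
    # the tumor position relative to the planned position is truth - match
    corrected_truth = truth_centroid.shifted(-online_match)

    # ---- gated delivery --------------------------------------------------
    t_tx0 = sc.setup_scan_start_s + scan_dur + sc.treatment_gap_s
    tx_sel = rpm.t >= t_tx0
    rpm_tx = RpmTrace(rpm.t[tx_sel], rpm.ext[tx_sel], rpm.gate_on[tx_sel])
    gates = delivery.gate_open_intervals(rpm_tx, gating_cfg)
    timeline = delivery.simulate_delivery(
        plan,
        gates,
        sc.rates,
        true_offset_s=sc.machine_clock_offset_s,
        seed=int(rng.integers(2**31)),
    )

    # ---- post-treatment CBCT + correlation model -------------------------
    t_post0 = float(timeline.gating_end_s[-1]) + sc.post_gap_s
    proj_post = scan(t_post0)
    est_post, _, rpm_cbct_offset = analyze_scan(proj_post)
    est_post_corr = est_post.shifted(-online_match)
    model = ecm.fit_ecm(rpm, est_post_corr)

    # ---- machine-log synchronization + per-spot tumor positions ----------
    off, scl = delivery.synchronize_machine_log(
        timeline, gates, offset_range_s=(0.0, 2.0 * sc.machine_clock_offset_s + 5.0)
    )
    s_g, e_g = timeline.reconstruct_gating_times(off, scl)
    est_full = ecm.apply_ecm(model, rpm)
    spot_pos = delivery.tumor_position_per_spot(s_g, e_g, est_full)

    # ---- dose reconstruction --------------------------------------------
    dose_planned = dose.compute_dose(plan, sc.phantom)
    dose_recon = dose.reconstruct_fraction_dose(plan, spot_pos, sc.phantom)
    ctv = sc.phantom.ctv_mask()
    dvh_plan = dose.dvh_metrics(dose_planned, ctv)
    dvh_rec = dose.dvh_metrics(dose_recon, ctv)

    # ---- metrics ----------------------------------------------------------
    drift = report.baseline_drift(est_setup, est_post)
    tx_stats = report.treatment_error_stats(spot_pos)
    field_sel = (corrected_truth.t >= timeline.gating_start_s[0]) & (
        corrected_truth.t <= timeline.gating_end_s[-1]
    )
    tx_truth = Trace3D(corrected_truth.t[field_sel], corrected_truth.pos[field_sel])
    beam_on = np.zeros(tx_truth.t.size, dtype=bool)
    i0 = np.searchsorted(tx_truth.t, timeline.gating_start_s)
    i1 = np.searchsorted(tx_truth.t, timeline.gating_end_s)
    for a, b in zip(i0, i1):
        beam_on[a:b] = True
    # spot intervals are short; make sure the per-spot samples count too
    beam_on_range = report.motion_range(tx_truth, beam_on) if beam_on.sum() >= 2 else (
        report.motion_range(Trace3D(np.arange(spot_pos.shape[0]) * 0.01 + 1.0, spot_pos))
    )
    frac_report = report.build_fraction_report(
        online_registration_error_mm=reg_err,
        baseline_drift_mm=drift,
        ecm_rms_mm=model.rms_fit_mm,
        treatment_error=tx_stats,
        motion_range_beam_on_mm=beam_on_range,
        motion_range_full_mm=report.motion_range(tx_truth),
        dvh_planned=dvh_plan,
        dvh_reconstructed=dvh_rec,
        extras={
            "achieved_duty": gating_cfg.achieved_duty,
            "recovered_offset_s": off,
            "true_offset_s": timeline.true_offset_s,
            "recovered_scale": scl,
            "true_scale": timeline.true_scale,
        },
    )
    return FractionResult(
        rpm=rpm,
        truth_tumor=corrected_truth,
        est_tumor_post=est_post_corr,
        ecm_model=model,
        gating=gating_cfg,
        timeline=timeline,
        recovered_offset_s=off,
        recovered_scale=scl,
        rpm_cbct_offset_s=rpm_cbct_offset,
        per_spot_positions_mm=spot_pos,
        plan=plan,
        dose_planned=dose_planned,
        dose_reconstructed=dose_recon,
        fraction_report=frac_report,
    )
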