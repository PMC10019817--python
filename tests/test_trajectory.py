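import numpy as np
import pytest

from gatedose import cbct, motion, trajectory
from gatedose.cbct import ScannerGeometry, project_point, simulate_cbct
from gatedose.motion import BreathingParams, GroundTruthEcm
from gatedose.traces import Trace3D
from gatedose.trajectory import (
    GaussianPdf3D,
    backproject_ray,
    centroid_trajectory,
    estimate_3d_trajectory,
    fit_position_pdf,
)

GEOM = ScannerGeometry(n_proj=200, scan_duration_s=30.0)


def _ray_distance(origin, direction, p):
    v = np.asarray(p) - origin
    return np.linalg.norm(v - (v @ direction) * direction)


class TestBackprojection:
    def test_panel_origin_ray_passes_isocenter(self):
        o, d = backproject_ray(GEOM, 73.0, (0.0, 0.0))
        assert _ray_distance(o, d, (0, 0, 0)) < 1e-9

    def test_projection_backprojection_round_trip(self, rng):
        for _ in range(25):
            p = rng.normal(0, 40, 3)
            ang = rng.uniform(0, 360)
            uv = project_point(GEOM, ang, p)
            o, d = backproject_ray(GEOM, ang, uv)
            assert _ray_distance(o, d, p) < 1e-9

    def test_two_views_triangulate_the_point(self, rng):
        p = np.array([8.0, -3.0, 12.0])
        rays = [backproject_ray(GEOM, a, project_point(GEOM, a, p)) for a in (30.0, 120.0)]
        # closed-form least-squares intersection of the two rays
        A = np.zeros((3, 3))
        b = np.zeros(3)
        for o, d in rays:
            P = np.eye(3) - np.outer(d, d)
            A += P
            b += P @ o
        x = np.linalg.solve(A, b)
        assert np.allclose(x, p, atol=1e-9)


class TestFit:
    def test_static_marker_recovers_point_with_vanishing_spread(self):
        p = np.array([3.0, -2.0, 7.0])
        tr = Trace3D(np.linspace(0, 30, 40), np.tile(p, (40, 1)))
        pdf = fit_position_pdf(simulate_cbct(GEOM, [tr]), GEOM, n_starts=1)
        assert np.allclose(pdf.mean, p, atol=1e-3)
        assert np.abs(pdf.cov).max() < 1e-6

    def test_gaussian_cloud_moments_recovered(self):
        geom = ScannerGeometry(n_proj=1000, scan_duration_s=30.0)
        rng = np.random.default_rng(0)
        mean = np.array([2.0, -4.0, 1.0])
        cov = np.diag([4.0, 25.0, 9.0])
        samples = rng.multivariate_normal(mean, cov, size=geom.n_proj + 1)
        # timestamps match the scan sampling exactly, so each projection
        # observes one cloud sample (full 360 deg arc, no noise)
        t = np.append(np.linspace(0, 30, geom.n_proj, endpoint=False), 30.0)
        proj = simulate_cbct(geom, [Trace3D(t, samples)])
        pdf = fit_position_pdf(proj, geom, n_starts=1)
        seen = samples[:-1]
        sample_cov = np.cov(seen.T, bias=True)
        assert np.allclose(pdf.mean, seen.mean(axis=0), atol=0.1)
        assert np.allclose(np.diag(pdf.cov), np.diag(sample_cov), rtol=0.05, atol=0.3)

    def test_small_instance_beats_brute_force_grid(self, rng):
        # 20 projections; independent NLL implementation with isotropic
        # covariance over a coarse 3D mean grid must not beat the ML fit
        geom = ScannerGeometry(n_proj=20, scan_duration_s=5.0)
        samples = rng.normal([1.0, -2.0, 3.0], 2.0, size=(20, 3))
        tr = Trace3D(np.linspace(-1, 7, 20), samples)
        proj = simulate_cbct(geom, [tr])
        pdf = fit_position_pdf(proj, geom, n_starts=3)

        rays = [backproject_ray(geom, proj.angle_deg[i], proj.uv_mm[i, 0]) for i in range(20)]

        def nll(mu, sigma2, cov=None):
            cov = sigma2 * np.eye(3) if cov is None else cov
            total = 0.0
            for o, d in rays:
                E = np.linalg.svd(np.eye(3) - np.outer(d, d))[0][:, :2]
                S = E.T @ cov @ E
                r = E.T @ (np.asarray(o) - mu)
                total += 0.5 * (np.log(np.linalg.det(S)) + r @ np.linalg.solve(S, r))
            return total

        grid = np.linspace(-3, 7, 9)
        best = np.inf
        for gx in grid:
            for gy in grid:
                for gz in grid:
                    for s2 in (1.0, 4.0, 9.0):
                        best = min(best, nll(np.array([gx, gy, gz]), s2))
        assert nll(pdf.mean, None, cov=pdf.cov) <= best + 1e-6

    def test_too_few_projections_rejected(self):
        tr = Trace3D(np.linspace(0, 30, 10), np.zeros((10, 3)))
        proj = simulate_cbct(GEOM, [tr], detect_prob=0.0, seed=0)
        with pytest.raises(ValueError):
            fit_position_pdf(proj, GEOM)

    def test_narrow_arc_warns(self):
        geom = ScannerGeometry(n_proj=20, scan_duration_s=5.0, arc_deg=60.0)
        tr = Trace3D(np.linspace(0, 5, 10), np.zeros((10, 3)))
        proj = simulate_cbct(geom, [tr])
        with pytest.warns(UserWarning):
            pdf = fit_position_pdf(proj, geom, n_starts=1)
        assert pdf.narrow_arc

    def test_accepted_iterates_never_increase_nll(self):
        rpm = motion.generate_external_trace(BreathingParams(seed=9), 35.0)
        tr = motion.apply_ground_truth_ecm(rpm, GroundTruthEcm())
        pdf = fit_position_pdf(simulate_cbct(GEOM, [tr]), GEOM, n_starts=1)
        assert np.all(np.diff(pdf.nll_history) <= 1e-9)


class TestConditioning:
    def test_estimates_reproject_onto_observations(self):
        rpm = motion.generate_external_trace(BreathingParams(seed=2), 35.0)
        tr = motion.apply_ground_truth_ecm(rpm, GroundTruthEcm())
        proj = simulate_cbct(GEOM, [tr], noise_sd_px=0.5, seed=0)
        pdf = fit_position_pdf(proj, GEOM, n_starts=1)
        est = estimate_3d_trajectory(proj, GEOM, pdf)
        for i in range(0, GEOM.n_proj, 17):
            uv = project_point(GEOM, proj.angle_deg[i], est.pos[i])
            assert np.abs(uv - proj.uv_mm[i, 0]).max() < 1e-9

    def test_conditional_mean_matches_1d_quadrature(self, rng):
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + 0.5 * np.eye(3)
        pdf = GaussianPdf3D(rng.normal(size=3) * 5, cov)
        cov_inv = np.linalg.inv(cov)
        for _ in range(10):
            o, d = backproject_ray(GEOM, rng.uniform(0, 360), rng.normal(0, 5, 2))
            est, _ = trajectory._condition_on_ray(pdf, o, d)
            s0 = (pdf.mean - o) @ d
            s = np.linspace(s0 - 80, s0 + 80, 200001)
            pts = o[None, :] + s[:, None] * d[None, :]
            r = pts - pdf.mean
            w = np.exp(-0.5 * np.einsum("ni,ij,nj->n", r, cov_inv, r))
            est_q = o + (np.sum(s * w) / np.sum(w)) * d
            assert np.abs(est - est_q).max() < 1e-6

    def test_isotropic_pdf_yields_closest_ray_point(self):
        pdf = GaussianPdf3D(np.array([5.0, 1.0, -2.0]), 4.0 * np.eye(3))
        o, d = backproject_ray(GEOM, 42.0, (0.0, 0.0))
        est, _ = trajectory._condition_on_ray(pdf, o, d)
        v = pdf.mean - o
        closest = o + (v @ d) * d
        assert np.allclose(est, closest, atol=1e-9)

    def test_breathing_trace_rms_error_below_1mm_noiseless(self):
        geom = ScannerGeometry(n_proj=1000, scan_duration_s=60.0)
        rpm = motion.generate_external_trace(
            BreathingParams(period_sd=0.2, amp_mm=(3, 15, 8), seed=5), 70.0
        )
        tr = motion.apply_ground_truth_ecm(rpm, GroundTruthEcm())
        proj = simulate_cbct(geom, [tr])
        pdf = fit_position_pdf(proj, geom, n_starts=1)
        est = estimate_3d_trajectory(proj, geom, pdf)
        err = est.pos - tr.interp(proj.t)
        rms_3d = np.sqrt(np.mean(np.sum(err**2, axis=1)))
        assert rms_3d < 1.0


class TestCentroid:
    def test_single_marker_identity(self):
        tr = Trace3D([0, 1], np.arange(6.0).reshape(2, 3))
        out = centroid_trajectory([tr])
        assert np.array_equal(out.pos, tr.pos)

    def test_symmetric_offsets_average_to_center(self):
        t = [0, 1, 2]
        base = np.arange(9.0).reshape(3, 3)
        a = Trace3D(t, base + [5, 0, 0])
        b = Trace3D(t, base - [5, 0, 0])
        assert np.allclose(centroid_trajectory([a, b]).pos, base)

    def test_missing_marker_handling(self):
        t = [0, 1]
        a = Trace3D(t, np.array([[1.0, 0, 0], [1.0, 0, 0]]))
        pos_b = np.array([[3.0, 0, 0], [np.nan, np.nan, np.nan]])
        b = Trace3D(t, pos_b)
        partial = centroid_trajectory([a, b])
        assert np.allclose(partial.pos[0], [2, 0, 0])
        assert np.allclose(partial.pos[1], [1, 0, 0])  # mean over detected only
        strict = centroid_trajectory([a, b], require_all=True)
        assert np.isnan(strict.pos[1]).all()


def test_seeded_noisy_scans_track_cc_motion():
    """Median CC RMS trajectory error stays well below the accuracy scale
    needed for correlation-model building (0.5 px detection noise)."""
    geom = ScannerGeometry(n_proj=300, scan_duration_s=60.0)
    rms_cc = []
    for seed in range(20):
        rpm = motion.generate_external_trace(BreathingParams(seed=200 + seed), 70.0)
        tr = motion.apply_ground_truth_ecm(rpm, GroundTruthEcm())
        proj = simulate_cbct(geom, [tr], noise_sd_px=0.5, seed=seed)
        pdf = fit_position_pdf(proj, geom, n_starts=1, seed=seed)
        est = estimate_3d_trajectory(proj, geom, pdf)
        err = est.pos - tr.interp(proj.t)
        rms_cc.append(np.sqrt(np.nanmean(err[:, 1] ** 2)))
    assert np.median(rms_cc) < 1.5
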