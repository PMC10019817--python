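import numpy as np
import pytest

from gatedose import delivery, dose, motion
from gatedose.delivery import (
    DeliveryRates,
    GatingConfig,
    apply_gating,
    calibrate_gating_window,
    gate_open_intervals,
    simulate_delivery,
    synchronize_machine_log,
    synchronize_rpm_cbct,
    tumor_position_per_spot,
)
from gatedose.motion import BreathingParams, GroundTruthEcm
from gatedose.traces import RpmTrace, Trace3D


def _line_plan(n=60, mu=30.0, spacing=4.0):
    """Single-layer plan with sub-threshold moves (no intrinsic pauses)."""
    return dose.SpotPlan(
        field=np.zeros(n, dtype=int),
        layer=np.zeros(n, dtype=int),
        energy_mev=np.full(n, 100.0),
        x_bev=spacing * np.arange(n, dtype=float),
        y_bev=np.zeros(n),
        mu=np.full(n, mu),
        gantry_angles_deg=np.array([0.0]),
    )


@pytest.fixture()
def gated_rpm(jittered_breathing):
    rpm = motion.generate_external_trace(jittered_breathing, 600.0)
    cfg = calibrate_gating_window(rpm, 0.5)
    return apply_gating(rpm, cfg), cfg


class TestCalibration:
    def test_regular_trace_reaches_half_duty(self, regular_breathing):
        rpm = motion.generate_external_trace(regular_breathing, 300.0)
        cfg = calibrate_gating_window(rpm, duty_target=0.5)
        assert 0.48 <= cfg.achieved_duty <= 0.52

    def test_full_duty_spans_signal_range(self, regular_breathing):
        rpm = motion.generate_external_trace(regular_breathing, 300.0)
        cfg = calibrate_gating_window(rpm, duty_target=1.0)
        assert cfg.window_lo <= rpm.ext.min()
        assert cfg.window_hi >= rpm.ext.max()
        assert cfg.achieved_duty == pytest.approx(1.0)

    def test_duty_monotone_in_lower_bound(self, regular_breathing):
        rpm = motion.generate_external_trace(regular_breathing, 300.0)
        cfg = calibrate_gating_window(rpm, duty_target=0.5)
        hi = cfg.window_hi

        def duty(lo):
            return np.mean((rpm.ext >= lo) & (rpm.ext <= hi))

        los = np.linspace(rpm.ext.min(), hi, 30)
        duties = [duty(lo) for lo in los]
        assert np.all(np.diff(duties) <= 1e-12)

    def test_flat_signal_rejected(self):
        rpm = RpmTrace(np.arange(0, 30, 0.04), np.zeros(750))
        with pytest.raises(ValueError):
            calibrate_gating_window(rpm)


class TestGateOpen:
    def _rpm_with_gate(self, lo, hi):
        t = np.arange(0, 20, 0.04)
        gate = (t >= lo) & (t < hi)
        return RpmTrace(t, np.zeros_like(t), gate)

    def test_latencies_shift_window_into_gate(self):
        cfg = GatingConfig(window_lo=-1, window_hi=1)
        go = gate_open_intervals(self._rpm_with_gate(10.0, 12.0), cfg)
        assert go.shape == (1, 2)
        assert go[0] == pytest.approx([10.24, 12.08])

    def test_short_gate_produces_no_beam_permission(self):
        cfg = GatingConfig(window_lo=-1, window_hi=1)
        go = gate_open_intervals(self._rpm_with_gate(10.0, 10.12), cfg)
        assert go.size == 0

    def test_zero_latencies_reproduce_gate_on(self):
        cfg = GatingConfig(window_lo=-1, window_hi=1, gate_on_latency_s=0, gate_off_latency_s=0)
        go = gate_open_intervals(self._rpm_with_gate(10.0, 12.0), cfg)
        assert go[0] == pytest.approx([10.0, 12.0])

    def test_endpoints_snap_to_log_grid(self, gated_rpm):
        rpm, cfg = gated_rpm
        go = gate_open_intervals(rpm, cfg)
        assert np.allclose(np.round(go / 0.04), go / 0.04, atol=1e-6)


class TestSimulateDelivery:
    def test_always_open_gate_additivity(self):
        plan = _line_plan()
        rates = DeliveryRates(pause_jitter_sd_s=0.0)
        gates = np.array([[0.0, 1e5]])
        tl = simulate_delivery(plan, gates, rates, true_scale=1.0)
        expect = plan.mu.sum() / rates.mu_per_s  # no pauses: moves below threshold
        assert tl.gating_end_s[-1] - tl.gating_start_s[0] == pytest.approx(expect)

    def test_half_duty_roughly_doubles_makespan(self, regular_breathing):
        # short spots keep the gate-end packing waste well below a cycle
        plan = _line_plan(n=800, mu=15.0)
        rates = DeliveryRates(pause_jitter_sd_s=0.0)
        rpm = motion.generate_external_trace(regular_breathing, 600.0)
        cfg = calibrate_gating_window(rpm, 0.5)
        # zero latencies: the gate-open fraction then equals the duty cycle
        cfg0 = GatingConfig(cfg.window_lo, cfg.window_hi, 0.0, 0.0)
        gates = gate_open_intervals(apply_gating(rpm, cfg0), cfg0)
        tl = simulate_delivery(plan, gates, rates, true_scale=1.0)
        open_span = plan.mu.sum() / rates.mu_per_s
        gated_span = tl.gating_end_s[-1] - tl.gating_start_s[0]
        assert gated_span == pytest.approx(2.0 * open_span, abs=2 * regular_breathing.period_s)

    def test_every_spot_inside_a_gate(self, gated_rpm, toy_plan):
        rpm, cfg = gated_rpm
        gates = gate_open_intervals(rpm, cfg)
        tl = simulate_delivery(toy_plan, gates, seed=0)
        ga, gb = gates[:, 0], gates[:, 1]
        i = np.searchsorted(ga, tl.gating_start_s, side="right") - 1
        assert np.all(i >= 0)
        assert np.all(tl.gating_end_s <= gb[i] + 1e-9)

    def test_beam_on_fraction_bounded_by_duty(self, gated_rpm, toy_plan):
        rpm, cfg = gated_rpm
        gates = gate_open_intervals(rpm, cfg)
        tl = simulate_delivery(toy_plan, gates, seed=0)
        frac = tl.spot_durations().sum() / (tl.gating_end_s[-1] - tl.gating_start_s[0])
        assert frac <= cfg.achieved_duty + 0.02

    def test_undeliverable_plan_rejected_with_remaining_count(self):
        plan = _line_plan(n=10, mu=500.0)
        gates = np.array([[0.0, 1.0]])  # too short for ten 1.7 s spots
        with pytest.raises(ValueError, match="spots remaining"):
            simulate_delivery(plan, gates, DeliveryRates(pause_jitter_sd_s=0.0))


class TestMachineLogSync:
    def test_known_offset_and_scale_recovered(self, gated_rpm, toy_plan):
        rpm, cfg = gated_rpm
        gates = gate_open_intervals(rpm, cfg)
        tl = simulate_delivery(toy_plan, gates, true_offset_s=13.37, true_scale=1.02, seed=1)
        off, scl = synchronize_machine_log(tl, gates, offset_range_s=(0, 30))
        assert off == pytest.approx(13.37, abs=0.04)
        assert scl == pytest.approx(1.02, abs=0.005)

    def test_zero_offset_unit_scale_recovered(self, gated_rpm, toy_plan):
        rpm, cfg = gated_rpm
        gates = gate_open_intervals(rpm, cfg)
        tl = simulate_delivery(toy_plan, gates, true_offset_s=0.0, true_scale=1.0, seed=2)
        off, scl = synchronize_machine_log(tl, gates, offset_range_s=(-5, 15))
        assert off == pytest.approx(0.0, abs=0.04)
        assert scl == pytest.approx(1.0, abs=0.005)

    def test_non_gated_delivery_cannot_be_synchronized(self):
        plan = _line_plan()
        gates = np.array([[0.0, 1e5]])
        tl = simulate_delivery(plan, gates, DeliveryRates(pause_jitter_sd_s=0.0))
        with pytest.raises(ValueError, match="gate"):
            synchronize_machine_log(tl, gates)


class TestRpmCbctSync:
    def test_self_alignment_is_zero(self, jittered_breathing):
        rpm = motion.generate_external_trace(jittered_breathing, 300.0)
        pos = np.zeros((rpm.t.size, 3))
        pos[:, 2] = rpm.ext
        assert synchronize_rpm_cbct(rpm, Trace3D(rpm.t, pos)) == pytest.approx(0.0, abs=1e-6)

    def test_known_clock_shift_recovered(self, jittered_breathing):
        rpm = motion.generate_external_trace(jittered_breathing, 300.0)
        pos = np.zeros((rpm.t.size, 3))
        pos[:, 2] = rpm.ext
        m = (rpm.t >= 100) & (rpm.t <= 160)
        sphere = Trace3D(rpm.t[m] - 2.0, pos[m])  # CBCT clock runs 2 s behind
        off = synchronize_rpm_cbct(rpm, sphere, search_s=30.0)
        assert off == pytest.approx(2.0, abs=0.02)

    def test_amplitude_rescaling_leaves_offset_unchanged(self, jittered_breathing):
        rpm = motion.generate_external_trace(jittered_breathing, 300.0)
        pos = np.zeros((rpm.t.size, 3))
        pos[:, 2] = 3.7 * rpm.ext + 12.0
        m = (rpm.t >= 100) & (rpm.t <= 160)
        sphere = Trace3D(rpm.t[m] - 2.0, pos[m])
        off = synchronize_rpm_cbct(rpm, sphere, search_s=30.0)
        assert off == pytest.approx(2.0, abs=0.02)


class TestPerSpotPositions:
    def test_static_trace_gives_identical_positions(self):
        est = Trace3D(np.linspace(0, 100, 50), np.tile([1.0, 2.0, 3.0], (50, 1)))
        pos = tumor_position_per_spot(np.array([10.0, 20.0]), np.array([10.5, 20.5]), est)
        assert np.allclose(pos, [1.0, 2.0, 3.0])

    def test_linear_drift_sampled_at_midtimes(self):
        t = np.linspace(0, 100, 201)
        est = Trace3D(t, np.stack([t, 2 * t, np.zeros_like(t)], axis=1))
        starts = np.array([10.0, 40.0])
        ends = np.array([12.0, 44.0])
        pos = tumor_position_per_spot(starts, ends, est)
        mids = 0.5 * (starts + ends)
        assert np.allclose(pos[:, 0], mids)
        assert np.allclose(pos[:, 1], 2 * mids)

    def test_uncovered_spots_reported_by_index(self):
        est = Trace3D(np.linspace(0, 10, 11), np.zeros((11, 3)))
        with pytest.raises(ValueError, match="spots"):
            tumor_position_per_spot(np.array([5.0, 50.0]), np.array([5.1, 50.1]), est)
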