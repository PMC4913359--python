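"""Limit-cycle detection, contrast decoding, confidence, ticks, pursuit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import clpsim as cs
from clpsim.percept import (
    confidence_residual_correlation,
    per_cycle_confidence,
)

from conftest import make_synthetic_trajectory


class TestDetectLimitCycle:
    def test_synthetic_sinusoid_cycle(self):
        t = np.arange(0.0, 10.0 + 1e-9, 1e-3)
        traj = make_synthetic_trajectory(t, np.sin(2 * np.pi * t), np.cos(2 * np.pi * t))
        s = cs.detect_limit_cycle(traj)
        assert s.converged
        assert s.period == pytest.approx(1.0, rel=1e-4)
        assert s.convergence_residual_series[-1] < 1e-6
        assert s.n1_amplitude == pytest.approx(1.0, rel=1e-3)

    def test_constant_trajectory_is_degenerate(self):
        t = np.arange(0.0, 5.0, 1e-3)
        traj = make_synthetic_trajectory(t, np.full_like(t, 0.3), np.full_like(t, 2.0))
        s = cs.detect_limit_cycle(traj)
        assert s.degenerate and not s.converged
        assert s.period is None

    def test_too_short_record_is_not_converged_but_not_an_error(self, params):
        traj = cs.run_ideal(0.7, params, cs.EngineConfig(duration=1.2))
        s = cs.detect_limit_cycle(traj)
        assert not s.converged
        assert s.period is None

    def test_ideal_mode_period_matches_analytic_prediction(
        self, params, ideal_summary
    ):
        pred = cs.vdp_predict(params, 0.7)
        assert ideal_summary.period == pytest.approx(pred.period_pred, rel=0.02)
        assert ideal_summary.n1_amplitude == pytest.approx(
            pred.n1_amplitude_pred, rel=0.03
        )


class TestDecodeContrast:
    def test_round_trip_at_half_contrast(self, params):
        traj = cs.run_ideal(0.5, params, cs.EngineConfig(duration=30.0))
        gamma_hat = cs.decode_contrast(cs.detect_limit_cycle(traj), params)
        assert abs(gamma_hat - 0.5) / 0.5 < 0.05

    def test_higher_contrast_decodes_higher_and_cycles_differ(self, params):
        """The 0.5- and 0.9-contrast runs land on distinct attractors."""
        out = {}
        for g in (0.5, 0.9):
            traj = cs.run_ideal(g, params, cs.EngineConfig(duration=30.0))
            s = cs.detect_limit_cycle(traj)
            out[g] = (cs.decode_contrast(s, params), s.period, s.omega_amplitude)
        assert out[0.9][0] > out[0.5][0]
        assert out[0.9][1] < out[0.5][1]  # faster cycle at higher contrast
        assert out[0.9][2] < out[0.5][2]  # smaller motor amplitude

    def test_recovery_sweep_ideal_mode(self, params):
        for g in np.arange(0.2, 1.01, 0.2):
            pred = cs.vdp_predict(params, float(g))
            eng = cs.EngineConfig(duration=max(30.0, 15 * pred.period_pred))
            s = cs.detect_limit_cycle(cs.run_ideal(float(g), params, eng))
            gamma_hat = cs.decode_contrast(s, params)
            assert abs(gamma_hat - g) / g < 0.05

    def test_decode_refuses_unconverged_summary(self, params):
        traj = cs.run_ideal(0.7, params, cs.EngineConfig(duration=1.2))
        with pytest.raises(ValueError):
            cs.decode_contrast(cs.detect_limit_cycle(traj), params)


class TestConfidence:
    def test_asymptotic_cycle_has_near_unit_confidence(self, params):
        """Feeding the converged tail alone: the self-model error vanishes."""
        run = cs.run_ideal(0.7, params, cs.EngineConfig(duration=50.0))
        i0 = 35000  # deep in the converged regime
        tail = cs.Trajectory(
            t=run.t[i0:] - run.t[i0],
            omega=run.omega[i0:],
            n1=run.n1[i0:],
            r_on=run.r_on[i0:],
            r_off=run.r_off[i0:],
            azimuth=run.azimuth[i0:],
            params=params,
            engine=run.engine,
            mode="ideal",
            gamma=0.7,
        )
        conf = cs.confidence(tail, params)
        settled = conf[2000:]  # past the first cycles of the segment
        assert np.all(settled >= 0.99)

    def test_confidence_rises_monotonically_during_convergence(self, params):
        eng = cs.EngineConfig(duration=30.0, initial_omega=40.0, initial_n1=0.0)
        traj = cs.run_ideal(0.7, params, eng)
        s = cs.detect_limit_cycle(traj)
        conf = cs.confidence(traj, params)
        pc = per_cycle_confidence(traj, s, conf)
        rho, _ = stats.spearmanr(np.arange(len(pc)), pc)
        assert rho > 0.9

    def test_confidence_tracks_convergence_residual(self, params, ideal_run):
        s = cs.detect_limit_cycle(ideal_run)
        conf = cs.confidence(ideal_run, params)
        assert confidence_residual_correlation(ideal_run, s, conf) < -0.9

    def test_replay_confidence_plateaus_below_closed_loop(
        self, default_scene, params, sensor_config, sensor_run
    ):
        """A decoupled motor trace leaves a persistent prediction error."""
        scene9 = cs.make_edge_scene(0.9, 0.5)
        rep = cs.run_replay(
            scene9, sensor_run, params, sensor_config, cs.EngineConfig(duration=30.0)
        )
        conf_closed = cs.confidence(sensor_run, params)
        conf_rep = cs.confidence(rep, params)
        assert conf_rep[-5000:].mean() < conf_closed[-5000:].mean() - 0.1

    def test_confidence_zero_before_first_interaction(
        self, params, sensor_config
    ):
        # edge enters the field only after ~1 s of blind rotation
        scene = cs.make_edge_scene(
            0.7, 0.5, edge_azimuth_deg=40.0, field_wrap="bounded",
            screen_center_deg=40.0, screen_halfwidth_deg=15.0,
        )
        eng = cs.EngineConfig(duration=10.0, initial_omega=10.0)
        traj = cs.run_sensor(scene, params, sensor_config, eng)
        conf = cs.confidence(traj, params)
        first = np.nonzero(traj.r_on + traj.r_off)[0][0]
        assert first > 100
        assert np.all(conf[:first] == 0.0)


class TestDecide:
    def test_threshold_never_reached(self):
        assert cs.decide(np.full(100, 0.5), 0.6) is None

    def test_linear_ramp_crossing_time(self):
        t = np.linspace(0.0, 10.0, 1001)
        assert cs.decide(t / 10.0, 0.7, t=t) == pytest.approx(7.0, abs=1e-6)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 1.5])
    def test_threshold_domain_error(self, bad):
        with pytest.raises(ValueError):
            cs.decide(np.linspace(0, 1, 10), bad)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=50))
    def test_first_crossing_semantics(self, values):
        c = np.asarray(values)
        out = cs.decide(c, 0.5)
        if out is None:
            assert np.all(c < 0.5)
        else:
            i = np.nonzero(c >= 0.5)[0][0]
            assert out <= i


class TestPerceptualTicks:
    def test_three_sinusoid_periods_count_three(self):
        t = np.arange(0.0, 3.0 + 1e-9, 1e-3)
        traj = make_synthetic_trajectory(t, np.sin(2 * np.pi * t), np.cos(2 * np.pi * t))
        s = cs.detect_limit_cycle(traj)
        assert cs.perceptual_ticks(traj, s) == 3

    def test_subperiod_record_counts_zero(self):
        t = np.arange(0.0, 0.6, 1e-3)
        traj = make_synthetic_trajectory(t, np.sin(2 * np.pi * t), np.cos(2 * np.pi * t))
        s = cs.detect_limit_cycle(traj)
        s2 = cs.LimitCycleSummary(
            period=1.0, n1_amplitude=None, omega_amplitude=None, cycle_samples=None,
            convergence_residual_series=np.empty(0), converged=False,
            crossing_times=s.crossing_times,
        )
        assert cs.perceptual_ticks(traj, s2) == 0

    def test_tick_count_times_period_matches_duration(self, ideal_run, ideal_summary):
        ticks = cs.perceptual_ticks(ideal_run, ideal_summary)
        assert ticks >= 1
        assert abs(ticks * ideal_summary.period - ideal_run.duration) <= ideal_summary.period


class TestDetectPursuit:
    @staticmethod
    def _plateau_trace():
        dt = 1e-3
        t = np.arange(0.0, 3.0, dt)
        w = np.where(t < 1.0, 5.0, np.where(t < 2.0, 5.0 - 10.0 * (t - 1.0), -5.0))
        return make_synthetic_trajectory(t, np.sin(t), w)

    def test_two_plateaus_two_dwells(self):
        dwells = cs.detect_pursuit(self._plateau_trace(), min_dwell=0.3, flatness=5.0)
        assert len(dwells) == 2
        assert dwells[0].mean_omega == pytest.approx(5.0, abs=0.2)
        assert dwells[1].mean_omega == pytest.approx(-5.0, abs=0.2)

    def test_constant_velocity_is_one_dwell_spanning_the_record(self):
        t = np.arange(0.0, 2.0, 1e-3)
        traj = make_synthetic_trajectory(t, np.sin(t), np.full_like(t, 7.0))
        dwells = cs.detect_pursuit(traj, min_dwell=0.3, flatness=5.0)
        assert len(dwells) == 1
        assert dwells[0].duration == pytest.approx(traj.duration, rel=0.02)
        assert dwells[0].mean_omega == pytest.approx(7.0)

    def test_static_edge_run_has_no_false_pursuit(self, sensor_run):
        """Oscillation about a static edge must not register as pursuit."""
        dwells = cs.detect_pursuit(sensor_run, min_dwell=0.3, flatness=5.0)
        assert all(abs(d.mean_omega) <= 1.0 for d in dwells)

    def test_moving_edge_run_dwells_at_stimulus_velocity(self):
        """The emergent smooth-pursuit experiment (triangle-wave edge)."""
        from clpsim.fixtures import (
            PURSUIT_EDGE_SPEED,
            PURSUIT_GAMMA,
            PURSUIT_HALF_PERIOD,
            pursuit_params,
        )

        scene = cs.make_edge_scene(
            PURSUIT_GAMMA, 0.5,
            edge_velocity_deg_s=PURSUIT_EDGE_SPEED,
            motion_half_period_s=PURSUIT_HALF_PERIOD,
        )
        traj = cs.run_sensor(
            scene, pursuit_params(), cs.SensorConfig(), cs.EngineConfig(duration=32.0)
        )
        dwells = cs.detect_pursuit(traj, min_dwell=0.3, flatness=5.0)
        v = PURSUIT_EDGE_SPEED
        pos = [d.mean_omega for d in dwells if d.mean_omega > 0]
        neg = [d.mean_omega for d in dwells if d.mean_omega < 0]
        assert pos and neg
        assert abs(np.mean(pos) - v) <= 0.2 * v
        assert abs(np.mean(neg) + v) <= 0.2 * v


def test_full_pipeline_produces_complete_percept(params, ideal_run):
    summary, percept = cs.analyze(ideal_run, params)
    assert summary.converged
    assert abs(percept.gamma_hat - 0.7) / 0.7 < 0.05
    assert percept.decision_time is not None
    assert percept.ticks >= 20
    assert 0.0 <= percept.confidence_series.min() <= percept.confidence_series.max() < 1.0
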