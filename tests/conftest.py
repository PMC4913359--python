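import numpy as np
import pytest

import clpsim as cs


@pytest.fixture(scope="session")
def params():
    return cs.LoopParams()


@pytest.fixture(scope="session")
def default_scene():
    return cs.make_edge_scene(0.7, 0.5)


@pytest.fixture(scope="session")
def sensor_config():
    return cs.SensorConfig()


@pytest.fixture(scope="session")
def ideal_run(params):
    """Standard 30 s ideal-mode run at gamma = 0.7."""
    return cs.run_ideal(0.7, params, cs.EngineConfig(duration=30.0))


@pytest.fixture(scope="session")
def ideal_summary(ideal_run):
    return cs.detect_limit_cycle(ideal_run)


@pytest.fixture(scope="session")
def sensor_run(default_scene, params, sensor_config):
    """Standard 30 s sensor-mode run at gamma = 0.7."""
    return cs.run_sensor(default_scene, params, sensor_config, cs.EngineConfig(duration=30.0))


def make_synthetic_trajectory(
    t, n1, omega, params=None, rate_window=0.01, r_on=None, r_off=None
):
    """Wrap raw arrays into a Trajectory for analysis-level tests."""
    t = np.asarray(t, dtype=float)
    p = params or cs.LoopParams()
    dt = float(t[1] - t[0])
    eng = cs.EngineConfig(
        dt=dt, rate_window=max(rate_window, dt), duration=float(t[-1] - t[0])
    )
    omega = np.asarray(omega, dtype=float)
    zero = np.zeros_like(t)
    az = np.concatenate(([0.0], np.cumsum(0.5 * (omega[1:] + omega[:-1]) * dt)))
    return cs.Trajectory(
        t=t,
        omega=omega,
        n1=np.asarray(n1, dtype=float),
        r_on=zero if r_on is None else np.asarray(r_on, dtype=float),
        r_off=zero if r_off is None else np.asarray(r_off, dtype=float),
        azimuth=az,
        params=p,
        engine=eng,
        mode="ideal",
    )
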