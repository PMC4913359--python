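"""Closed-loop simulation engine.

Three run modes close (or deliberately open) the loop:

* ``ideal``  — the sensory stage is replaced by its closed-form contingency
  ``r_on - r_off = C1*gamma*omega`` and the two loop ODEs are integrated
  directly (fixed-step RK4 by default).
* ``sensor`` — the camera pans at the instantaneous motor velocity, the
  event simulator produces ON/OFF events, and the event rates measured over
  each ``rate_window`` drive the next window's integration (zero-order hold
  with one window of sensory latency, Euler substeps within windows).
* ``replay`` — the motor variable follows a previously recorded trace; the
  sensory input no longer influences the motion.  This is the in-silico
  open-loop (motor-sensory open-loop) ablation: the motor-to-sensory arc is
  intact but the sensory-to-motor arc is cut.

The actuator clamp ``|omega| <= omega_max`` is applied after every step; the
pan azimuth is the trapezoidal time-integral of the recorded (clamped)
motor velocity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .dynamics import LoopParams, LoopState
from .scene import Scene
from .sensor import DvsSimulator, SensorConfig

TRAJECTORY_CSV_HEADER = ["t_s", "omega_deg_s", "n1", "r_on", "r_off", "azimuth_deg"]


class EngineConfig(BaseModel):
    """Integration settings for a closed-loop run."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    dt: float = Field(1e-3, gt=0.0)
    rate_window: float = Field(0.01, gt=0.0)
    duration: float = Field(30.0, gt=0.0)
    initial_omega: float = 10.0
    initial_n1: float = 0.0
    initial_azimuth_deg: float = 0.0
    integrator: str = Field("rk4", pattern="^(rk4|euler)$")
    seed: int = 0

    @model_validator(mode="after")
    def _check_windows(self):
        if self.rate_window < self.dt - 1e-12:
            raise ValueError("rate_window must be >= dt")
        ratio = self.rate_window / self.dt
        if abs(ratio - round(ratio)) > 1e-6:
            raise ValueError("rate_window must be an integer multiple of dt")
        if self.duration < self.rate_window:
            raise ValueError("duration must be >= rate_window")
        return self


@dataclass
class Trajectory:
    """Uniformly sampled record of a closed-loop run."""

    t: np.ndarray
    omega: np.ndarray
    n1: np.ndarray
    r_on: np.ndarray
    r_off: np.ndarray
    azimuth: np.ndarray
    params: LoopParams
    engine: EngineConfig
    mode: str
    scene: Scene | None = None
    sensor: SensorConfig | None = None
    gamma: float | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def state_at(self, i: int) -> LoopState:
        return LoopState(
            t=float(self.t[i]),
            omega=float(self.omega[i]),
            n1=float(self.n1[i]),
            r_on=float(self.r_on[i]),
            r_off=float(self.r_off[i]),
        )

    def to_csv(self, path) -> None:
        """Write the time series as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame(
            {
                "t_s": self.t,
                "omega_deg_s": self.omega,
                "n1": self.n1,
                "r_on": self.r_on,
                "r_off": self.r_off,
                "azimuth_deg": self.azimuth,
            }
        ).to_csv(path, index=False)
        meta = {
            "mode": self.mode,
            "gamma": self.gamma,
            "params": self.params.model_dump(),
            "engine": self.engine.model_dump(),
            "scene": self.scene.model_dump() if self.scene else None,
            "sensor": self.sensor.model_dump() if self.sensor else None,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        path = Path(path)
        df = pd.read_csv(path)
        if list(df.columns) != TRAJECTORY_CSV_HEADER:
            raise ValueError(
                f"expected columns {TRAJECTORY_CSV_HEADER}, got {list(df.columns)}"
            )
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            t=df["t_s"].to_numpy(),
            omega=df["omega_deg_s"].to_numpy(),
            n1=df["n1"].to_numpy(),
            r_on=df["r_on"].to_numpy(),
            r_off=df["r_off"].to_numpy(),
            azimuth=df["azimuth_deg"].to_numpy(),
            params=LoopParams(**meta["params"]),
            engine=EngineConfig(**meta["engine"]),
            mode=meta["mode"],
            scene=Scene(**meta["scene"]) if meta.get("scene") else None,
            sensor=SensorConfig(**meta["sensor"]) if meta.get("sensor") else None,
            gamma=meta.get("gamma"),
        )


def perturb(
    state: LoopState,
    delta: tuple[float, float],
    params: LoopParams,
) -> LoopState:
    """Offset (omega, n1) by ``delta`` and re-apply the actuator clamp."""
    d_omega, d_n1 = delta
    omega = state.omega + d_omega
    omega = max(-params.omega_max, min(params.omega_max, omega))
    return LoopState(
        t=state.t, omega=omega, n1=state.n1 + d_n1, r_on=state.r_on, r_off=state.r_off
    )


def _check_finite(n1: float, omega: float, k: int, t: float) -> None:
    if not (math.isfinite(n1) and math.isfinite(omega)):
        raise RuntimeError(f"non-finite loop state at step {k} (t = {t:.6g} s)")


def run_ideal(
    gamma: float,
    params: LoopParams,
    engine: EngineConfig,
    initial_state: tuple[float, float] | None = None,
) -> Trajectory:
    """Integrate the pure ODE loop with the analytic sensory contingency.

    ``initial_state`` overrides the engine's (omega, n1) starting point.
    """
    if gamma < 0.0:
        raise ValueError("gamma must be non-negative")
    dt = engine.dt
    n_steps = int(round(engine.duration / dt))
    c2, c3, c4, mu = params.c2, params.c3, params.c4, params.mu
    kq = params.c1 * gamma  # rate difference per unit omega
    w_max = params.omega_max

    omega = engine.initial_omega if initial_state is None else initial_state[0]
    n1 = engine.initial_n1 if initial_state is None else initial_state[1]
    omega = max(-w_max, min(w_max, omega))

    t_arr = np.arange(n_steps + 1) * dt
    w_arr = np.empty(n_steps + 1)
    n_arr = np.empty(n_steps + 1)
    use_rk4 = engine.integrator == "rk4"

    def deriv(n1_, w_):
        return c2 * kq * w_, mu * (1.0 - c4 * n1_ * n1_) * w_ - n1_ / c3

    for k in range(n_steps + 1):
        w_arr[k], n_arr[k] = omega, n1
        if k == n_steps:
            break
        if use_rk4:
            k1n, k1w = deriv(n1, omega)
            k2n, k2w = deriv(n1 + 0.5 * dt * k1n, omega + 0.5 * dt * k1w)
            k3n, k3w = deriv(n1 + 0.5 * dt * k2n, omega + 0.5 * dt * k2w)
            k4n, k4w = deriv(n1 + dt * k3n, omega + dt * k3w)
            n1 += dt / 6.0 * (k1n + 2 * k2n + 2 * k3n + k4n)
            omega += dt / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
        else:
            dn, dw = deriv(n1, omega)
            n1 += dt * dn
            omega += dt * dw
        omega = max(-w_max, min(w_max, omega))
        _check_finite(n1, omega, k + 1, (k + 1) * dt)

    rd = kq * w_arr
    azimuth = engine.initial_azimuth_deg + _trapezoid_integral(w_arr, dt)
    return Trajectory(
        t=t_arr,
        omega=w_arr,
        n1=n_arr,
        r_on=np.maximum(rd, 0.0),
        r_off=np.maximum(-rd, 0.0),
        azimuth=azimuth,
        params=params,
        engine=engine,
        mode="ideal",
        gamma=gamma,
    )


def _trapezoid_integral(w: np.ndarray, dt: float) -> np.ndarray:
    out = np.empty_like(w)
    out[0] = 0.0
    np.cumsum(0.5 * (w[1:] + w[:-1]) * dt, out=out[1:])
    return out


def run_sensor(
    scene: Scene,
    params: LoopParams,
    sensor: SensorConfig,
    engine: EngineConfig,
    initial_state: tuple[float, float] | None = None,
) -> Trajectory:
    """Close the loop through the simulated event camera.

    Per ``rate_window``: the camera pans with the evolving motor velocity
    and events are collected at every integration substep; at the window's
    end the ON/OFF rates are computed and held constant (zero-order hold)
    to drive the integration over the *next* window — one window of sensory
    latency, as in a sampled robot controller.  Substeps use Euler (the held
    rates are step inputs, so higher order buys nothing).
    """
    if engine.dt > sensor.sample_dt_s * (1 + 1e-9):
        raise ValueError("engine dt must not exceed the sensor sampling interval")
    jitter_sensor = sensor
    if sensor.jitter_seed is not None:
        # derive the jitter stream from the engine seed for reproducibility
        jitter_sensor = sensor.model_copy(
            update={"jitter_seed": (engine.seed * 9973 + sensor.jitter_seed) % (2**31)}
        )
    rng = (
        np.random.default_rng(jitter_sensor.jitter_seed)
        if jitter_sensor.jitter_seed is not None
        else None
    )

    dt = engine.dt
    n_sub = int(round(engine.rate_window / dt))
    n_steps = int(round(engine.duration / dt))
    n_windows = int(math.ceil(n_steps / n_sub))
    c2, c3, c4, mu = params.c2, params.c3, params.c4, params.mu
    w_max = params.omega_max

    omega = engine.initial_omega if initial_state is None else initial_state[0]
    n1 = engine.initial_n1 if initial_state is None else initial_state[1]
    omega = max(-w_max, min(w_max, omega))
    theta = engine.initial_azimuth_deg

    t_arr = np.arange(n_steps + 1) * dt
    w_arr = np.empty(n_steps + 1)
    n_arr = np.empty(n_steps + 1)
    ron_arr = np.empty(n_steps + 1)
    roff_arr = np.empty(n_steps + 1)
    az_arr = np.empty(n_steps + 1)

    dvs = DvsSimulator(scene, sensor)
    dvs.process(np.array([0.0]), np.array([theta]))  # initialise pixel references
    held_on = held_off = 0.0

    k = 0
    w_arr[0], n_arr[0], az_arr[0] = omega, n1, theta
    ron_arr[0], roff_arr[0] = held_on, held_off
    for _w in range(n_windows):
        sub = min(n_sub, n_steps - k)
        if sub <= 0:
            break
        t_win = t_arr[k : k + sub + 1]
        az_win = np.empty(sub + 1)
        az_win[0] = theta
        for j in range(sub):
            rd = held_on - held_off
            dn = c2 * rd
            dw = mu * (1.0 - c4 * n1 * n1) * omega - n1 / c3
            w_prev = omega
            n1 += dt * dn
            omega += dt * dw
            omega = max(-w_max, min(w_max, omega))
            theta += 0.5 * (w_prev + omega) * dt
            k += 1
            w_arr[k], n_arr[k], az_arr[k] = omega, n1, theta
            ron_arr[k], roff_arr[k] = held_on, held_off
            az_win[j + 1] = theta
            _check_finite(n1, omega, k, t_arr[k])
        times, _, pols = dvs.process(t_win[1:], az_win[1:])
        if rng is not None and len(times):
            times = times + rng.normal(0.0, jitter_sensor.jitter_std_s, len(times))
            inside = (times >= t_win[0]) & (times <= t_win[-1])
            pols = pols[inside]
        window_s = sub * dt
        held_on = float(np.sum(pols == 1)) / window_s
        held_off = float(np.sum(pols == -1)) / window_s

    return Trajectory(
        t=t_arr,
        omega=w_arr,
        n1=n_arr,
        r_on=ron_arr,
        r_off=roff_arr,
        azimuth=az_arr,
        params=params,
        engine=engine,
        mode="sensor",
        scene=scene,
        sensor=sensor,
        gamma=scene.gamma,
    )


def run_replay(
    scene: Scene,
    recorded_omega: "Trajectory | tuple[np.ndarray, np.ndarray]",
    params: LoopParams,
    sensor: SensorConfig,
    engine: EngineConfig,
    initial_n1: float | None = None,
) -> Trajectory:
    """Open-loop motor playback: omega follows the recording exactly.

    The neuronal variable still integrates the (event-derived) sensory
    rates, but the sensory input has no influence on the motion — the
    sensory-to-motor arc is cut.  Raises ``ValueError`` if the recording
    does not cover the configured duration.
    """
    if isinstance(recorded_omega, Trajectory):
        rec_t, rec_w = recorded_omega.t, recorded_omega.omega
    else:
        rec_t, rec_w = (np.asarray(a, dtype=float) for a in recorded_omega)
    if rec_t[-1] - rec_t[0] < engine.duration - 1e-9:
        raise ValueError("recorded trajectory shorter than the requested duration")

    dt = engine.dt
    n_steps = int(round(engine.duration / dt))
    n_sub = int(round(engine.rate_window / dt))
    t_arr = np.arange(n_steps + 1) * dt
    # re-sample the recording onto this engine's time grid, t=0 at its start
    w_arr = np.interp(t_arr, rec_t - rec_t[0], rec_w)
    w_arr = np.clip(w_arr, -params.omega_max, params.omega_max)
    az_arr = engine.initial_azimuth_deg + _trapezoid_integral(w_arr, dt)

    n1 = engine.initial_n1 if initial_n1 is None else initial_n1
    n_arr = np.empty(n_steps + 1)
    ron_arr = np.empty(n_steps + 1)
    roff_arr = np.empty(n_steps + 1)

    dvs = DvsSimulator(scene, sensor)
    dvs.process(t_arr[:1], az_arr[:1])
    held_on = held_off = 0.0
    n_arr[0], ron_arr[0], roff_arr[0] = n1, held_on, held_off
    k = 0
    while k < n_steps:
        sub = min(n_sub, n_steps - k)
        for j in range(sub):
            n1 += dt * params.c2 * (held_on - held_off)
            k += 1
            n_arr[k], ron_arr[k], roff_arr[k] = n1, held_on, held_off
            _check_finite(n1, w_arr[k], k, t_arr[k])
        times, _, pols = dvs.process(t_arr[k - sub + 1 : k + 1], az_arr[k - sub + 1 : k + 1])
        window_s = sub * dt
        held_on = float(np.sum(pols == 1)) / window_s
        held_off = float(np.sum(pols == -1)) / window_s

    return Trajectory(
        t=t_arr,
        omega=w_arr,
        n1=n_arr,
        r_on=ron_arr,
        r_off=roff_arr,
        azimuth=az_arr,
        params=params,
        engine=engine,
        mode="replay",
        scene=scene,
        sensor=sensor,
        gamma=scene.gamma,
    )
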