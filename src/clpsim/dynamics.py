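"""Motor-sensory-motor (MSM) loop dynamics.

The general closed-loop scheme is

    s = f(m, u)        sensory variables, memoryless in s
    dn/dt = g(n, s)    neuronal dynamics
    dm/dt = h(m, n)    motor dynamics,

with the environment state ``u`` entering only through ``f``.  The concrete
contrast-perceiving loop uses a single motor variable (pan velocity
``omega``, deg/s), a single neuronal variable (``n1``, the integrated
ON/OFF event-count difference) and the sensory pair ``(r_on, r_off)``:

    dn1/dt    = C2 * (r_on - r_off)
    domega/dt = mu * (1 - C4*n1**2) * omega - n1 / C3

Substituting the ideal sensory contingency ``r_on - r_off = C1*gamma*omega``
and rescaling ``x = sqrt(C4) * n1`` turns the pair into the classical Van
der Pol oscillator

    x'' - mu*(1 - x**2)*x' + omega0**2 * x = 0,
    omega0 = sqrt(C1*C2*gamma / C3),

so for any positive contrast and positive constants the loop converges to a
unique limit cycle whose period and amplitudes encode the contrast: in the
weakly nonlinear regime (mu << omega0) the cycle is near-sinusoidal with
period 2*pi/omega0, |x| amplitude 2 (hence |n1| amplitude 2/sqrt(C4)) and
|omega| amplitude 2/(sqrt(C4)*sqrt(C1*C2*C3*gamma)).

Default constants: C1 = 2*mean_luminance/(event_threshold*pixel_pitch) for
the default sensor (= 4000/7); C2 and C3 are set so that the cycle
frequency at gamma = 0.7 is exactly 2*pi rad/s (a 1 s perceptual cycle) and
the omega amplitude there is 20 deg/s; C4 = 4 scales the n1 amplitude to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

#: default sensory gain: 2 * 0.5 / (0.005 * 0.35) events/s per deg/s
DEFAULT_C1 = 4000.0 / 7.0
#: default neuronal gain, sets omega0(gamma=0.7) = 2*pi rad/s given C1, C3
DEFAULT_C2 = math.pi / 4000.0
#: default motor time-constant parameter (s); sets omega amplitude 20 deg/s
DEFAULT_C3 = 1.0 / (40.0 * math.pi)
#: default amplitude normalisation, n1 amplitude = 2/sqrt(C4) = 1
DEFAULT_C4 = 4.0


class LoopParams(BaseModel):
    """Constants of the contrast-perceiving MSM loop (all positive)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    c1: float = Field(DEFAULT_C1, gt=0.0, description="sensory gain, ev/s per deg/s")
    c2: float = Field(DEFAULT_C2, gt=0.0, description="neuronal integration gain")
    c3: float = Field(DEFAULT_C3, gt=0.0, description="motor time constant (s)")
    c4: float = Field(DEFAULT_C4, gt=0.0, description="amplitude normalisation (1/n1^2)")
    mu: float = Field(0.3, gt=0.0, description="relaxation/nonlinearity parameter (1/s)")
    omega_max: float = Field(120.0, gt=0.0, description="actuator clamp on |omega| (deg/s)")


@dataclass
class LoopState:
    """Instantaneous state of the loop."""

    t: float
    omega: float
    n1: float
    r_on: float = 0.0
    r_off: float = 0.0


@dataclass
class VdpPrediction:
    """Small-mu analytic characterisation of the limit cycle."""

    omega0: float  # rad/s
    period_pred: float  # s
    n1_amplitude_pred: float
    omega_amplitude_pred: float  # deg/s


def loop_rhs(
    state: LoopState, rate_difference: float, params: LoopParams
) -> tuple[float, float]:
    """Time derivatives (dn1/dt, domega/dt); no actuator clamp applied here."""
    if not (math.isfinite(state.n1) and math.isfinite(state.omega)):
        raise ValueError("non-finite loop state")
    dn1 = params.c2 * rate_difference
    domega = (
        params.mu * (1.0 - params.c4 * state.n1**2) * state.omega
        - state.n1 / params.c3
    )
    return dn1, domega


def vdp_predict(params: LoopParams, gamma: float) -> VdpPrediction:
    """Analytic small-mu limit-cycle prediction for contrast ``gamma``.

    Valid for ``mu`` well below ``omega0``; used as the analytic oracle for
    the numerical integration and as the seed of the contrast decoder.
    """
    if gamma <= 0.0:
        raise ValueError("analytic prediction requires gamma > 0")
    omega0 = math.sqrt(params.c1 * params.c2 * gamma / params.c3)
    n1_amp = 2.0 / math.sqrt(params.c4)
    omega_amp = 2.0 / (
        math.sqrt(params.c4) * math.sqrt(params.c1 * params.c2 * params.c3 * gamma)
    )
    return VdpPrediction(
        omega0=omega0,
        period_pred=2.0 * math.pi / omega0,
        n1_amplitude_pred=n1_amp,
        omega_amplitude_pred=omega_amp,
    )


class ClosedLoopSystem:
    """A closed dynamical system composed from the maps f, g and h.

    The full state is ``(m, n)``; the sensory vector ``s`` is computed
    algebraically from ``s = f(m, u)`` at every evaluation (no intrinsic
    sensory dynamics).  ``u`` is an arbitrary object describing the
    environment (may be ``None`` when the loop is open: with ``f`` returning
    zeros the neuronal stage is decoupled from the world).
    """

    def __init__(
        self,
        f: Callable,
        g: Callable,
        h: Callable,
        dim_m: int = 1,
        dim_n: int = 1,
        dim_s: int | None = None,
    ):
        self.f, self.g, self.h = f, g, h
        self.dim_m, self.dim_n = int(dim_m), int(dim_n)
        m0 = np.zeros(self.dim_m)
        n0 = np.zeros(self.dim_n)
        s0 = np.atleast_1d(np.asarray(f(m0, None), dtype=float))
        if dim_s is not None and s0.shape != (dim_s,):
            raise ValueError(f"f returned shape {s0.shape}, expected ({dim_s},)")
        self.dim_s = len(s0)
        if np.atleast_1d(np.asarray(g(n0, s0), dtype=float)).shape != (self.dim_n,):
            raise ValueError("g must return dn/dt with the dimension of n")
        if np.atleast_1d(np.asarray(h(m0, n0), dtype=float)).shape != (self.dim_m,):
            raise ValueError("h must return dm/dt with the dimension of m")

    def rhs(self, m: np.ndarray, n: np.ndarray, u=None):
        s = np.atleast_1d(np.asarray(self.f(m, u), dtype=float))
        dm = np.atleast_1d(np.asarray(self.h(m, n), dtype=float))
        dn = np.atleast_1d(np.asarray(self.g(n, s), dtype=float))
        return dm, dn, s

    def integrate(
        self,
        m0: Sequence[float],
        n0: Sequence[float],
        duration: float,
        dt: float,
        u=None,
    ):
        """Fixed-step RK4 integration; returns (t, m, n, s) sample arrays."""
        n_steps = int(round(duration / dt))
        m = np.atleast_1d(np.asarray(m0, dtype=float)).copy()
        n = np.atleast_1d(np.asarray(n0, dtype=float)).copy()
        t_out = np.empty(n_steps + 1)
        m_out = np.empty((n_steps + 1, self.dim_m))
        n_out = np.empty((n_steps + 1, self.dim_n))
        s_out = np.empty((n_steps + 1, self.dim_s))
        for k in range(n_steps + 1):
            dm, dn, s = self.rhs(m, n, u)
            t_out[k], m_out[k], n_out[k], s_out[k] = k * dt, m, n, s
            if k == n_steps:
                break
            k1m, k1n = dm, dn
            k2m, k2n, _ = self.rhs(m + 0.5 * dt * k1m, n + 0.5 * dt * k1n, u)
            k3m, k3n, _ = self.rhs(m + 0.5 * dt * k2m, n + 0.5 * dt * k2n, u)
            k4m, k4n, _ = self.rhs(m + dt * k3m, n + dt * k3n, u)
            m = m + dt / 6.0 * (k1m + 2 * k2m + 2 * k3m + k4m)
            n = n + dt / 6.0 * (k1n + 2 * k2n + 2 * k3n + k4n)
        return t_out, m_out, n_out, s_out


def compose_loop(
    f: Callable,
    g: Callable,
    h: Callable,
    dim_m: int = 1,
    dim_n: int = 1,
    dim_s: int | None = None,
) -> ClosedLoopSystem:
    """Compose sensory, neuronal and motor maps into a closed system.

    Raises ``ValueError`` if the dimensions of the supplied maps do not
    match.
    """
    return ClosedLoopSystem(f, g, h, dim_m=dim_m, dim_n=dim_n, dim_s=dim_s)


def contrast_loop_maps(params: LoopParams, gamma: float):
    """The (f, g, h) triple of the contrast model, for ``compose_loop``.

    ``u`` is ignored by ``f`` (the contrast enters as a fixed parameter);
    passing ``f = lambda m, u: np.zeros(2)`` instead models the open
    ex-afferent loop with no object in the field.
    """

    def f(m, u):
        rd = params.c1 * gamma * m[0]
        return np.array([max(rd, 0.0), max(-rd, 0.0)])

    def g(n, s):
        return np.array([params.c2 * (s[0] - s[1])])

    def h(m, n):
        return np.array(
            [params.mu * (1.0 - params.c4 * n[0] ** 2) * m[0] - n[0] / params.c3]
        )

    return f, g, h
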