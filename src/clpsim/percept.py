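"""Percept extraction from closed-loop trajectories.

The perceptual attractor is the limit cycle in the (n1, omega) phase plane.
This module detects it, measures its period and amplitudes, decodes the
external contrast from the asymptotic period, tracks a convergence
confidence signal, converts the confidence into a decision time, counts
perceptual-time ticks (completed loop cycles) and finds smooth-pursuit
dwell segments in the motor trace.

Cycle bookkeeping: cycles are delimited by upward zero crossings of the
mean-removed n1 series (linear interpolation between samples).  Each cycle
is resampled onto a fixed 64-point phase grid and compared with its
predecessor by RMS distance in z-scored (n1, omega) coordinates — a
scale-free per-cycle convergence residual.  The run is deemed converged
when the final residual falls below the tolerance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dynamics import LoopParams, vdp_predict
from .engine import EngineConfig, Trajectory, run_ideal

PHASE_POINTS = 64


@dataclass
class LimitCycleSummary:
    """Geometry and convergence bookkeeping of the detected cycle."""

    period: float | None
    n1_amplitude: float | None
    omega_amplitude: float | None
    cycle_samples: np.ndarray | None  # (PHASE_POINTS, 2): columns n1, omega
    convergence_residual_series: np.ndarray
    converged: bool
    degenerate: bool = False
    crossing_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    cycle_periods: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_cycles(self) -> int:
        return max(len(self.crossing_times) - 1, 0)

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "n1_amplitude": self.n1_amplitude,
            "omega_amplitude": self.omega_amplitude,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "n_cycles": self.n_cycles,
            "convergence_residual_series": list(
                map(float, self.convergence_residual_series)
            ),
        }


@dataclass
class Percept:
    """Decoded feature estimate and the dynamics of reaching it."""

    gamma_hat: float | None
    confidence_series: np.ndarray
    decision_time: float | None
    ticks: int
    feature_id: str = "contrast"

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "gamma_hat": self.gamma_hat,
            "decision_time": self.decision_time,
            "ticks": int(self.ticks),
            "confidence_final": float(self.confidence_series[-1])
            if len(self.confidence_series)
            else None,
        }


def _upward_crossings(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Times where ``y`` crosses zero upward, linearly interpolated."""
    below = y[:-1] < 0.0
    atabove = y[1:] >= 0.0
    idx = np.nonzero(below & atabove)[0]
    frac = -y[idx] / (y[idx + 1] - y[idx])
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    if len(y) > 1 and y[0] == 0.0 and y[1] > 0.0:
        times = np.concatenate(([t[0]], times))
    return times


def detect_limit_cycle(
    traj: Trajectory,
    tolerance: float = 0.05,
    settle_fraction: float = 0.0,
) -> LimitCycleSummary:
    """Detect and characterise the limit cycle of a trajectory.

    Returns a non-converged summary (never raises) when fewer than two
    complete cycles are present, and flags constant trajectories as
    degenerate.  ``settle_fraction`` optionally drops an initial fraction of
    the record before analysis.
    """
    i0 = int(len(traj.t) * settle_fraction)
    t = traj.t[i0:]
    n1 = traj.n1[i0:]
    omega = traj.omega[i0:]

    s_n1, s_w = float(np.std(n1)), float(np.std(omega))
    if s_n1 < 1e-12 or s_w < 1e-12:
        return LimitCycleSummary(
            period=None,
            n1_amplitude=None,
            omega_amplitude=None,
            cycle_samples=None,
            convergence_residual_series=np.empty(0),
            converged=False,
            degenerate=True,
        )

    y = n1 - float(np.mean(n1))
    crossings = _upward_crossings(t, y)
    if len(crossings) < 3:  # fewer than 2 complete cycles
        return LimitCycleSummary(
            period=None,
            n1_amplitude=None,
            omega_amplitude=None,
            cycle_samples=None,
            convergence_residual_series=np.empty(0),
            converged=False,
            crossing_times=crossings,
        )

    m_n1, m_w = float(np.mean(n1)), float(np.mean(omega))
    phases = np.arange(PHASE_POINTS) / PHASE_POINTS
    cycles = []
    for a, b in zip(crossings[:-1], crossings[1:]):
        ts = a + phases * (b - a)
        zn = (np.interp(ts, t, n1) - m_n1) / s_n1
        zw = (np.interp(ts, t, omega) - m_w) / s_w
        cycles.append(np.column_stack([zn, zw]))
    residuals = np.array(
        [
            float(np.sqrt(np.mean((cycles[i] - cycles[i - 1]) ** 2)))
            for i in range(1, len(cycles))
        ]
    )
    periods = np.diff(crossings)
    n_avg = min(3, len(periods))
    period = float(np.mean(periods[-n_avg:]))

    a, b = crossings[-2], crossings[-1]
    sel = (t >= a) & (t <= b)
    n1_amp = float(np.max(n1[sel]) - np.min(n1[sel])) / 2.0
    w_amp = float(np.max(omega[sel]) - np.min(omega[sel])) / 2.0
    final = cycles[-1]
    final_raw = np.column_stack([final[:, 0] * s_n1 + m_n1, final[:, 1] * s_w + m_w])
    return LimitCycleSummary(
        period=period,
        n1_amplitude=n1_amp,
        omega_amplitude=w_amp,
        cycle_samples=final_raw,
        convergence_residual_series=residuals,
        converged=bool(residuals[-1] < tolerance),
        crossing_times=crossings,
        cycle_periods=periods,
    )


def _simulated_period(
    gamma: float, params: LoopParams, dt: float, n_periods: float = 8.0
) -> float:
    """Period of the ideal-mode cycle at ``gamma``, by short integration.

    Starts near the predicted cycle to keep the transient brief.
    """
    pred = vdp_predict(params, gamma)
    eng = EngineConfig(
        dt=dt,
        rate_window=dt,
        duration=max(n_periods * pred.period_pred, 10 * dt),
        initial_omega=min(pred.omega_amplitude_pred, params.omega_max * 0.9),
        initial_n1=0.0,
    )
    traj = run_ideal(gamma, params, eng)
    summary = detect_limit_cycle(traj, settle_fraction=0.4)
    if summary.period is None:
        raise RuntimeError(f"no cycle detected at gamma={gamma}")
    return summary.period


def decode_contrast(
    summary: LimitCycleSummary,
    params: LoopParams,
    refine: bool = True,
    refine_dt: float = 1e-3,
    refine_iters: int = 18,
) -> float:
    """Decode contrast from the asymptotic cycle period.

    Inverts the small-signal frequency relation ``omega0**2 =
    C1*C2*gamma/C3`` and, by default, refines the estimate by bisecting on
    the contrast whose simulated ideal-mode period matches the measured one
    (the small-mu inversion is biased at moderate mu).  Refuses (raises
    ``ValueError``) if the summary is not converged.
    """
    if not summary.converged or summary.period is None:
        raise ValueError("decode refused: limit-cycle summary not converged")
    t_meas = summary.period
    omega0 = 2.0 * math.pi / t_meas
    gamma0 = params.c3 * omega0**2 / (params.c1 * params.c2)
    gamma0 = min(max(gamma0, 0.0), 1.0)
    if not refine:
        return gamma0

    lo = max(min(gamma0 * 0.4, 1.0), 1e-3)
    hi = min(max(gamma0 * 2.5, lo * 1.01), 1.0)
    # periods decrease with contrast; widen the bracket if needed
    if _simulated_period(lo, params, refine_dt) < t_meas:
        return lo if lo > 1e-3 else 0.0
    if _simulated_period(hi, params, refine_dt) > t_meas:
        return hi
    for _ in range(refine_iters):
        mid = 0.5 * (lo + hi)
        if _simulated_period(mid, params, refine_dt) > t_meas:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def confidence(
    traj: Trajectory,
    params: LoopParams,
    sigma_dyn: float = 0.05,
    sigma_ret: float = 0.25,
) -> np.ndarray:
    """Perceptual confidence C_j(t) in [0, 1] from internal-model error.

    The internal model is the loop's own dynamics run ahead from the
    current state.  Two prediction horizons are combined: one
    ``rate_window`` ahead through the motor/neuronal equations driven by
    the recorded sensory rates (this error stays up whenever the motion is
    decoupled from the sensory input, as in replay), and one full cycle
    ahead under the prediction "the state revisits itself after one loop
    cycle" (this error decays as the limit cycle is approached and tracks
    the convergence residual).  Confidence is ``exp(-e_dyn/sigma_dyn -
    e_ret/sigma_ret)``, zero before the first sensory interaction and
    capped at 1 - 1e-6.
    """
    t, n1, w = traj.t, traj.n1, traj.omega
    n = len(t)
    dt = traj.dt
    K = max(int(round(traj.engine.rate_window / dt)), 1)
    s_n1 = max(float(np.std(n1)), 1e-12)
    s_w = max(float(np.std(w)), 1e-12)

    # --- one-window-ahead self-model ---------------------------------------
    rd = traj.r_on - traj.r_off
    c2, c3, c4, mu = params.c2, params.c3, params.c4, params.mu
    w_max = params.omega_max
    m = n - K
    e_dyn = np.zeros(n)
    if m > 0:
        n1_p = n1[:m].copy()
        w_p = w[:m].copy()
        for j in range(K):
            dn = c2 * rd[j : j + m]
            dw = mu * (1.0 - c4 * n1_p * n1_p) * w_p - n1_p / c3
            n1_p += dt * dn
            w_p += dt * dw
            np.clip(w_p, -w_max, w_max, out=w_p)
        err = np.sqrt(
            ((n1_p - n1[K:]) / s_n1) ** 2 / 2.0 + ((w_p - w[K:]) / s_w) ** 2 / 2.0
        )
        e_dyn[K:] = err
        e_dyn[:K] = err[0] if m else 0.0

    # --- one-cycle-ahead return error --------------------------------------
    y = n1 - float(np.mean(n1))
    crossings = _upward_crossings(t, y)
    e_ret = np.full(n, 3.0)  # large error before any full cycle has closed
    if len(crossings) >= 2:
        # local period: duration of the most recently completed cycle
        cyc_end = crossings[1:]
        cyc_per = np.diff(crossings)
        idx = np.searchsorted(cyc_end, t, side="right") - 1
        valid = idx >= 0
        per = np.where(valid, cyc_per[np.clip(idx, 0, len(cyc_per) - 1)], np.nan)
        t_back = t - per
        ok = valid & (t_back >= t[0])
        n1_b = np.interp(t_back[ok], t, n1)
        w_b = np.interp(t_back[ok], t, w)
        e_ret[ok] = np.sqrt(
            ((n1[ok] - n1_b) / s_n1) ** 2 / 2.0 + ((w[ok] - w_b) / s_w) ** 2 / 2.0
        )

    conf = np.exp(-(e_dyn / sigma_dyn) - (e_ret / sigma_ret))
    first = _first_interaction_index(traj)
    conf[:first] = 0.0
    return np.minimum(conf, 1.0 - 1e-6)


def _first_interaction_index(traj: Trajectory) -> int:
    """Index of the first sensory event (first nonzero ON/OFF rate)."""
    drive = traj.r_on + traj.r_off
    nz = np.nonzero(drive > 0.0)[0]
    return int(nz[0]) if len(nz) else len(traj.t)


def decide(
    confidence_series: np.ndarray,
    c_d: float,
    t: np.ndarray | None = None,
) -> float | None:
    """First time the confidence crosses the decision threshold ``C_d``.

    Returns ``None`` if the threshold is never reached.  ``t`` defaults to
    sample indices.
    """
    if not (0.0 < c_d < 1.0):
        raise ValueError("decision threshold C_d must lie strictly in (0, 1)")
    c = np.asarray(confidence_series, dtype=float)
    if t is None:
        t = np.arange(len(c), dtype=float)
    above = np.nonzero(c >= c_d)[0]
    if not len(above):
        return None
    i = above[0]
    if i == 0:
        return float(t[0])
    # linear interpolation of the crossing time
    frac = (c_d - c[i - 1]) / (c[i] - c[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def perceptual_ticks(traj: Trajectory, summary: LimitCycleSummary) -> int:
    """Completed loop cycles in the trajectory — the perceptual-time count.

    Cycles are zero-crossing delimited; leading/trailing partial segments
    that span a whole period (to 2% tolerance) are counted as completed
    cycles, so a record of exactly three sinusoid periods counts 3 ticks.
    """
    p = summary.period
    c = summary.crossing_times
    if (p is None or p <= 0) and len(c) >= 2:
        p = float(np.mean(np.diff(c)))
    if p is None or p <= 0:
        return 0
    if len(c) == 0:
        return int(math.floor(traj.duration / p + 0.02))
    ticks = len(c) - 1
    ticks += int(math.floor((c[0] - traj.t[0]) / p + 0.02))
    ticks += int(math.floor((traj.t[-1] - c[-1]) / p + 0.02))
    return max(ticks, 0)


@dataclass
class DwellSegment:
    """A constant-velocity (smooth-pursuit) segment of the motor trace."""

    t_start: float
    t_end: float
    mean_omega: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def detect_pursuit(
    traj: Trajectory,
    min_dwell: float = 0.3,
    flatness: float = 5.0,
    smooth_window: float | None = None,
) -> list[DwellSegment]:
    """Find maximal segments where the pan velocity stays flat.

    A dwell is a run of duration >= ``min_dwell`` where the smoothed
    |domega/dt| stays below ``flatness`` (deg/s^2).  Smoothing uses a
    moving average over ``smooth_window`` seconds (default: the engine's
    rate window).
    """
    if min_dwell <= 0:
        raise ValueError("min_dwell must be positive")
    t, w = traj.t, traj.omega
    dt = traj.dt
    acc = np.gradient(w, t)
    win = smooth_window if smooth_window is not None else traj.engine.rate_window
    k = max(int(round(win / dt)), 1)
    if k > 1:
        kernel = np.ones(k) / k
        acc = np.convolve(acc, kernel, mode="same")
    flat = np.abs(acc) < flatness
    segments: list[DwellSegment] = []
    i = 0
    n = len(flat)
    while i < n:
        if flat[i]:
            j = i
            while j + 1 < n and flat[j + 1]:
                j += 1
            if t[j] - t[i] >= min_dwell:
                segments.append(
                    DwellSegment(
                        t_start=float(t[i]),
                        t_end=float(t[j]),
                        mean_omega=float(np.mean(w[i : j + 1])),
                    )
                )
            i = j + 1
        else:
            i += 1
    return segments


def per_cycle_confidence(
    traj: Trajectory, summary: LimitCycleSummary, conf: np.ndarray
) -> np.ndarray:
    """Mean confidence within each completed cycle."""
    c = summary.crossing_times
    out = []
    for a, b in zip(c[:-1], c[1:]):
        sel = (traj.t >= a) & (traj.t < b)
        out.append(float(np.mean(conf[sel])))
    return np.array(out)


def confidence_residual_correlation(
    traj: Trajectory, summary: LimitCycleSummary, conf: np.ndarray
) -> float:
    """Spearman correlation between per-cycle confidence and residual."""
    pc = per_cycle_confidence(traj, summary, conf)[1:]
    res = summary.convergence_residual_series
    rho, _ = stats.spearmanr(pc, res)
    return float(rho)


def analyze(
    traj: Trajectory,
    params: LoopParams,
    tolerance: float = 0.05,
    c_d: float = 0.9,
    sigma_dyn: float = 0.05,
    sigma_ret: float = 0.25,
    refine_decode: bool = True,
) -> tuple[LimitCycleSummary, Percept]:
    """Full percept pipeline: cycle detection, decode, confidence, decision."""
    summary = detect_limit_cycle(traj, tolerance=tolerance)
    gamma_hat = None
    if summary.converged:
        gamma_hat = decode_contrast(summary, params, refine=refine_decode)
    conf = confidence(traj, params, sigma_dyn=sigma_dyn, sigma_ret=sigma_ret)
    decision = decide(conf, c_d, t=traj.t)
    ticks = perceptual_ticks(traj, summary)
    return summary, Percept(
        gamma_hat=gamma_hat,
        confidence_series=conf,
        decision_time=decision,
        ticks=ticks,
    )


def save_report(path, summary: LimitCycleSummary, percept: Percept) -> None:
    """Serialize an analysis report (summary + percept) as JSON."""
    with open(path, "w") as fh:
        json.dump(
            {"limit_cycle": summary.to_dict(), "percept": percept.to_dict()}, fh, indent=2
        )
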