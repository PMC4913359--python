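"""Event-based (DVS-like) sensor model.

A 1-D array of pixels rides on the pan axis.  Each pixel holds a reference
luminance; whenever the instantaneous luminance at the pixel's line of sight
departs from the reference by at least ``event_threshold``, the pixel emits
one event per threshold quantum — polarity +1 (ON) for increases, -1 (OFF)
for decreases — and moves its reference by the emitted quanta.  A static
sensor viewing a static scene therefore emits nothing, and a uniform
(zero-contrast) field emits nothing under any motion.

With this linear-threshold pixel, sweeping a contrast edge at angular
velocity ``omega`` across the array yields the closed-form sensory
contingency

    r_on - r_off = C1 * gamma * omega,
    C1 = 2 * mean_luminance / (event_threshold * pixel_pitch_deg),

because the edge crosses ``omega / pixel_pitch_deg`` pixels per second and
each crossing releases ``(L_bright - L_dark) / event_threshold`` events of a
single polarity.  (Real DVS pixels use a *logarithmic* threshold, which
would make the net rate proportional to ``log(L_bright/L_dark)`` instead of
``gamma``; the linear model keeps the contingency exactly linear in
contrast.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .scene import Scene

EVENT_CSV_HEADER = ["t_s", "pixel", "polarity"]


class SensorConfig(BaseModel):
    """Geometry and threshold of the simulated event camera."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    n_pixels: int = Field(128, ge=1)
    pixel_pitch_deg: float = Field(0.35, gt=0.0)
    event_threshold: float = Field(0.005, gt=0.0)
    sample_dt_s: float = Field(1e-3, gt=0.0)
    #: seed for optional Gaussian event-time jitter; ``None`` disables jitter
    jitter_seed: int | None = None
    jitter_std_s: float = Field(1e-4, ge=0.0)

    @property
    def field_of_view_deg(self) -> float:
        return self.n_pixels * self.pixel_pitch_deg

    def pixel_offsets_deg(self) -> np.ndarray:
        """Angular offset of each pixel centre from the optical axis."""
        idx = np.arange(self.n_pixels, dtype=float)
        return (idx - (self.n_pixels - 1) / 2.0) * self.pixel_pitch_deg


def sensory_gain(mean_luminance: float, config: SensorConfig) -> float:
    """Closed-form C1 for this sensor: 2*mean / (threshold * pitch)."""
    return 2.0 * mean_luminance / (config.event_threshold * config.pixel_pitch_deg)


@dataclass
class EventBatch:
    """Timestamped ON/OFF events over a time window."""

    times: np.ndarray
    pixels: np.ndarray
    polarities: np.ndarray
    window: tuple[float, float]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.pixels = np.asarray(self.pixels, dtype=int)
        self.polarities = np.asarray(self.polarities, dtype=int)
        if not (len(self.times) == len(self.pixels) == len(self.polarities)):
            raise ValueError("event arrays must have equal length")
        if len(self.times):
            if np.any(np.diff(self.times) < 0):
                raise ValueError("events must be sorted by time")
            t0, t1 = self.window
            if self.times[0] < t0 - 1e-12 or self.times[-1] > t1 + 1e-12:
                raise ValueError("event times must lie within the window")
            if not np.all(np.isin(self.polarities, (-1, 1))):
                raise ValueError("polarity must be +1 or -1")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def empty(cls, window: tuple[float, float]) -> "EventBatch":
        z = np.empty(0)
        return cls(z, z.astype(int), z.astype(int), window)

    @property
    def n_on(self) -> int:
        return int(np.sum(self.polarities == 1))

    @property
    def n_off(self) -> int:
        return int(np.sum(self.polarities == -1))

    @property
    def duration(self) -> float:
        return self.window[1] - self.window[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"t_s": self.times, "pixel": self.pixels, "polarity": self.polarities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, window: tuple[float, float] | None = None) -> "EventBatch":
        df = pd.read_csv(path)
        if list(df.columns) != EVENT_CSV_HEADER:
            raise ValueError(f"expected columns {EVENT_CSV_HEADER}, got {list(df.columns)}")
        t = df["t_s"].to_numpy()
        if window is None:
            window = (float(t[0]), float(t[-1])) if len(t) else (0.0, 0.0)
        return cls(t, df["pixel"].to_numpy(), df["polarity"].to_numpy(), window)


class DvsSimulator:
    """Stateful per-pixel threshold-crossing event generator.

    The pixel reference luminances persist across calls, so the simulator can
    be driven incrementally window by window inside the closed-loop engine.
    """

    def __init__(self, scene: Scene, config: SensorConfig):
        self.scene = scene
        self.config = config
        self._offsets = config.pixel_offsets_deg()
        self._ref: np.ndarray | None = None

    def process(self, t: np.ndarray, azimuth_deg: np.ndarray):
        """Feed pan samples; return (times, pixels, polarities) of new events.

        The first sample ever seen initialises the pixel references and emits
        nothing.
        """
        t = np.asarray(t, dtype=float)
        az = np.asarray(azimuth_deg, dtype=float)
        if t.shape != az.shape:
            raise ValueError("time and azimuth sample arrays must align")
        th = self.config.event_threshold
        ev_t, ev_px, ev_pol = [], [], []
        start = 0
        if self._ref is None and len(t):
            self._ref = np.array(
                self.scene.luminance(az[0] + self._offsets, float(t[0])), dtype=float
            )
            start = 1
        for k in range(start, len(t)):
            lum = self.scene.luminance(az[k] + self._offsets, float(t[k]))
            d = lum - self._ref
            # number of whole threshold quanta crossed, sign-aware; the small
            # epsilon absorbs float rounding when d is an exact multiple of th
            n_ev = np.floor(np.abs(d) / th + 1e-9).astype(int)
            hit = n_ev > 0
            if np.any(hit):
                pol = np.sign(d[hit]).astype(int)
                counts = n_ev[hit]
                ev_px.append(np.repeat(np.nonzero(hit)[0], counts))
                ev_pol.append(np.repeat(pol, counts))
                ev_t.append(np.full(int(counts.sum()), float(t[k])))
                self._ref[hit] += pol * counts * th
        if ev_t:
            return np.concatenate(ev_t), np.concatenate(ev_px), np.concatenate(ev_pol)
        z = np.empty(0)
        return z, z.astype(int), z.astype(int)


def generate_events(
    scene: Scene,
    pan_trajectory: tuple[np.ndarray, np.ndarray],
    config: SensorConfig,
    window: tuple[float, float] | None = None,
) -> EventBatch:
    """Simulate the event stream for a sampled pan trajectory.

    ``pan_trajectory`` is a pair of aligned arrays ``(t, azimuth_deg)``
    sampled no coarser than ``config.sample_dt_s``.  Events carry the
    timestamp of the sample at which the threshold crossing is detected.
    """
    t, az = (np.asarray(a, dtype=float) for a in pan_trajectory)
    if t.ndim != 1 or t.shape != az.shape or len(t) < 1:
        raise ValueError("pan trajectory must be two aligned 1-D arrays")
    if len(t) > 1 and np.max(np.diff(t)) > config.sample_dt_s * (1 + 1e-9):
        raise ValueError("pan trajectory sampled coarser than sample_dt_s")
    if window is None:
        window = (float(t[0]), float(t[-1]))
    if t[0] > window[0] + 1e-12 or t[-1] < window[1] - 1e-12:
        raise ValueError("pan trajectory does not cover the requested window")
    sim = DvsSimulator(scene, config)
    times, pixels, pols = sim.process(t, az)
    if config.jitter_seed is not None and len(times):
        rng = np.random.default_rng(config.jitter_seed)
        times = times + rng.normal(0.0, config.jitter_std_s, size=len(times))
        times = np.clip(times, window[0], window[1])
        order = np.argsort(times, kind="stable")
        times, pixels, pols = times[order], pixels[order], pols[order]
    return EventBatch(times, pixels, pols, window)


def event_rates(batch: EventBatch) -> tuple[float, float]:
    """ON and OFF event rates (events/s) integrated over the whole array."""
    if batch.duration <= 0.0:
        raise ValueError("event rates need a window of positive duration")
    return batch.n_on / batch.duration, batch.n_off / batch.duration


def analytic_rate_difference(gamma: float, omega: float, c1: float) -> float:
    """Ideal sensory contingency r_on - r_off = C1*gamma*omega (noise ignored)."""
    return c1 * gamma * omega
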