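"""Luminance scenes: the external state ``u`` seen by the sensor.

A scene is a one-dimensional (azimuthal) luminance field containing a single
contrast step ("edge") between a dark and a bright half-field.  Contrast is
Michelson contrast,

    gamma = (L_bright - L_dark) / (L_bright + L_dark),

with the two levels placed symmetrically around ``mean_luminance``, so that
``L_bright + L_dark = 2 * mean_luminance`` exactly.  The edge may translate,
either at a constant drift velocity or back and forth as a triangle wave.

Two wrap modes are supported: ``periodic`` repeats the dark/bright pattern
with a 360 deg period (the rising edge at ``edge_azimuth_deg`` and the
falling edge 180 deg away), while ``bounded`` models a finite screen —
outside the screen extent the field is uniform background at the mean
luminance, so a sensor pointed off-screen receives no contrast at all.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
from pydantic import BaseModel, ConfigDict, Field


class FieldWrap(str, Enum):
    periodic = "periodic"
    bounded = "bounded"


class Scene(BaseModel):
    """Azimuthal luminance field with a single contrast edge."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    gamma: float = Field(..., ge=0.0, le=1.0, description="Michelson contrast")
    mean_luminance: float = Field(..., gt=0.0)
    edge_azimuth_deg: float = 0.0
    edge_velocity_deg_s: float = 0.0
    #: half-period of triangle-wave (back and forth) edge motion; ``None``
    #: means constant drift at ``edge_velocity_deg_s``
    motion_half_period_s: float | None = Field(None, gt=0.0)
    field_wrap: FieldWrap = FieldWrap.periodic
    #: centre/extent of the screen; used only in bounded mode
    screen_center_deg: float = 0.0
    screen_halfwidth_deg: float = Field(90.0, gt=0.0)

    @property
    def l_dark(self) -> float:
        return self.mean_luminance * (1.0 - self.gamma)

    @property
    def l_bright(self) -> float:
        return self.mean_luminance * (1.0 + self.gamma)

    def edge_position_deg(self, t):
        """Edge azimuth at time ``t`` (scalar or array) under the motion law."""
        t = np.asarray(t, dtype=float)
        v = self.edge_velocity_deg_s
        if self.motion_half_period_s is None or v == 0.0:
            disp = v * t
        else:
            hp = self.motion_half_period_s
            phase = np.mod(t, 2.0 * hp)
            disp = np.where(phase < hp, v * phase, v * (2.0 * hp - phase))
        return self.edge_azimuth_deg + disp

    def luminance(self, azimuth_deg, t):
        """Luminance at ``azimuth_deg`` (scalar or array) and scalar time ``t``."""
        az = np.asarray(azimuth_deg, dtype=float)
        edge = self.edge_position_deg(t)
        rel = az - edge
        if self.field_wrap is FieldWrap.periodic:
            out = np.where(np.mod(rel, 360.0) < 180.0, self.l_bright, self.l_dark)
        else:
            on_screen = np.abs(az - self.screen_center_deg) <= self.screen_halfwidth_deg
            two_sided = np.where(rel >= 0.0, self.l_bright, self.l_dark)
            out = np.where(on_screen, two_sided, self.mean_luminance)
        if out.ndim == 0:
            return float(out)
        return out


def make_edge_scene(
    gamma: float,
    mean_luminance: float,
    edge_azimuth_deg: float = 0.0,
    edge_velocity_deg_s: float = 0.0,
    field_wrap: FieldWrap | str = FieldWrap.periodic,
    motion_half_period_s: float | None = None,
    screen_center_deg: float = 0.0,
    screen_halfwidth_deg: float = 90.0,
) -> Scene:
    """Build a contrast-edge :class:`Scene`.

    Raises a validation error (``ValueError`` subclass) for contrast outside
    [0, 1] or non-positive mean luminance.
    """
    return Scene(
        gamma=gamma,
        mean_luminance=mean_luminance,
        edge_azimuth_deg=edge_azimuth_deg,
        edge_velocity_deg_s=edge_velocity_deg_s,
        field_wrap=FieldWrap(field_wrap),
        motion_half_period_s=motion_half_period_s,
        screen_center_deg=screen_center_deg,
        screen_halfwidth_deg=screen_halfwidth_deg,
    )


def luminance_at(scene: Scene, azimuth_deg, t: float):
    """Evaluate the scene luminance ``u`` at a point and time."""
    return scene.luminance(azimuth_deg, t)
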