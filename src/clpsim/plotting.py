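"""Convenience plots: time series, phase portrait, occupancy heat map."""

from __future__ import annotations

import numpy as np

from .engine import Trajectory


def plot_time_series(traj: Trajectory, axes=None):
    """n1 and omega as functions of time (two stacked axes)."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    axes[0].plot(traj.t, traj.n1)
    axes[0].set_ylabel("n1")
    axes[1].plot(traj.t, traj.omega)
    axes[1].set_ylabel("omega (deg/s)")
    axes[1].set_xlabel("time (s)")
    return axes


def plot_phase(traj: Trajectory, ax=None):
    """Trajectory in the (n1, omega) phase plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot(traj.n1, traj.omega, lw=0.7)
    ax.set_xlabel("n1")
    ax.set_ylabel("omega (deg/s)")
    return ax


def plot_occupancy(traj: Trajectory, bins: int = 60, ax=None):
    """Time-occupancy heat map of the phase plane.

    Each bin is coloured by the time (s) the system spent in it; smooth
    pursuit shows up as hot spots at the stimulus velocity.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5))
    h, xe, ye = np.histogram2d(traj.n1, traj.omega, bins=bins)
    h *= traj.dt
    im = ax.pcolormesh(xe, ye, h.T, cmap="inferno")
    plt.colorbar(im, ax=ax, label="occupancy (s)")
    ax.set_xlabel("n1")
    ax.set_ylabel("omega (deg/s)")
    return ax
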