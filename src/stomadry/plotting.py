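"""Matplotlib glue for quick inspection of trajectories and fits."""

from __future__ import annotations

import numpy as np

from .fitting import FitResult
from .model import Trajectory
from .series import WaterContentSeries

__all__ = ["plot_trajectory", "plot_fit"]


def _shade_nights(ax, times_h: np.ndarray, light: np.ndarray) -> None:
    edges = np.flatnonzero(np.diff(light.astype(int)) != 0) + 1
    bounds = np.concatenate(([0], edges, [light.size - 1]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        if not light[a]:
            ax.axvspan(times_h[a] / 24.0, times_h[min(b, light.size - 1)] / 24.0,
                       color="0.85", zorder=0)


def plot_trajectory(traj: Trajectory, ax=None):
    """Water content over time with nights shaded and the wilt event marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    y = traj.water_wt_pct if traj.water_wt_pct is not None else traj.a_l
    _shade_nights(ax, traj.times_h, traj.light)
    ax.plot(traj.times_h / 24.0, y, color="seagreen", lw=1.2)
    if traj.wilt_time_h is not None:
        ax.axvline(traj.wilt_time_h / 24.0, color="firebrick", ls="--",
                   lw=0.8, label="wilting point")
        ax.legend(frameon=False)
    ax.set_xlabel("time since irrigation stop (d)")
    ax.set_ylabel("water content (wt%)" if traj.water_wt_pct is not None
                  else "leaf water amount")
    return ax


def plot_fit(series: WaterContentSeries, fit: FitResult, ax=None):
    """Measured series and the fitted model curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    _shade_nights(ax, series.times_h, series.light)
    ax.plot(series.times_h / 24.0, series.water_wt_pct, ".", ms=2,
            color="yellowgreen", label="measured")
    ax.plot(series.times_h / 24.0, fit.predicted, color="darkgreen",
            lw=1.3, label=f"model (R$^2$={fit.r_squared:.3f})")
    ax.set_xlabel("time since irrigation stop (d)")
    ax.set_ylabel("water content (wt%)")
    ax.legend(frameon=False)
    return ax
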