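"""Two-compartment soil-leaf water transport model with stomatal dynamics.

The plant-soil system is reduced to two water pools, the soil content A_s
and the leaf content A_l (arbitrary amount units), coupled by

    dA_l/dt =  k1 (A_s - A_l) - k2 A_l
    dA_s/dt = -k1 (A_s - A_l) - k3 A_s

k1 models root uptake driven by the soil-leaf content gradient.  While the
soil is wet, uptake balances transpiration, so k1 follows the equilibrium
value k2 A_l / (A_s - A_l); it saturates at k1_max (soil retention limits
the flux) and drops irreversibly to zero when the soil crosses the permanent
wilting point theta_wilt.

k2 is the stomatal loss coefficient.  Under drought the stomata open wide at
dawn and then close exponentially over the day:

    light:  k2(t) = (k2_os - k2_cs) exp(-s / tau) + k2_cs
    dark:   k2    = Gamma_bright_dark * k2_cs

with s the time since the most recent light onset (the decay restarts at
every dawn), k2_os the open-stomata and k2_cs the closed-stomata level, and
Gamma < 1 accounting for residual (cuticular) loss in darkness.  The
characteristic closure half-life is t_1/2 = tau ln 2.

k3 is a constant direct soil-evaporation coefficient.

The observable is the gravimetric leaf water content
wt% = 100 A_l / (A_l + m_dry) with a fixed leaf dry mass m_dry in the same
amount units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.signal import medfilt

from . import _kernel
from .series import WaterContentSeries

__all__ = [
    "LightSchedule",
    "DryingParams",
    "Trajectory",
    "PhaseOptions",
    "PhaseBoundaries",
    "k2_profile",
    "k1_rate",
    "simulate_drying",
    "simulate_wtpct",
    "half_life_from_tau",
    "segment_phases",
    "water_wt_pct_from_amount",
    "amount_from_water_wt_pct",
    "DEFAULT_DT_H",
]

DEFAULT_DT_H = 0.0125  # RK4 substep ceiling (45 s); transitions never straddled


@dataclass(frozen=True)
class LightSchedule:
    """Periodic photoperiod; defaults to the 12 h / 12 h growth cycle."""

    period_h: float = 24.0
    bright_h: float = 12.0
    t0_h: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.bright_h < self.period_h):
            raise ValueError("need 0 < bright_h < period_h")

    def is_light(self, t_h) -> np.ndarray:
        """Boolean light flag(s) at time(s) t_h."""
        phase = np.mod(np.asarray(t_h, dtype=float) - self.t0_h, self.period_h)
        return phase < self.bright_h

    def transitions(self, t_end_h: float) -> np.ndarray:
        """All light on/off switch times inside (0, t_end_h)."""
        k_lo = math.floor(-self.t0_h / self.period_h) - 1
        k_hi = math.ceil((t_end_h - self.t0_h) / self.period_h) + 1
        times = []
        for k in range(k_lo, k_hi + 1):
            for off in (0.0, self.bright_h):
                t = self.t0_h + off + k * self.period_h
                if 0.0 < t < t_end_h:
                    times.append(t)
        return np.array(sorted(times))


@dataclass(frozen=True)
class DryingParams:
    """Physiological parameter vector of one plant.

    Rates are per hour, tau_h in hours; a_l0/a_s0/theta_wilt share the
    model's arbitrary amount units.  k2_wilt_multiplier scales k2 after the
    wilting event (post-wilt loss can exceed the open-stomata level; kept at
    1 unless evidence says otherwise).
    """

    k1_max: float
    k3: float
    k2_os: float
    k2_cs: float
    tau_h: float
    gamma_bright_dark: float
    theta_wilt: float
    a_l0: float
    a_s0: float
    k2_wilt_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k1_max", "k3", "k2_os", "k2_cs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k2_os < self.k2_cs:
            raise ValueError("open-stomata rate k2_os must be >= k2_cs")
        if self.tau_h <= 0:
            raise ValueError("tau_h must be positive")
        if not (0 < self.gamma_bright_dark <= 1):
            raise ValueError("gamma_bright_dark must lie in (0, 1]")
        if not (self.a_s0 > self.a_l0 > 0):
            raise ValueError("need a_s0 > a_l0 > 0")
        if self.theta_wilt >= self.a_s0:
            raise ValueError("theta_wilt must lie below the initial soil pool")

    def with_(self, **kwargs) -> "DryingParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Trajectory:
    """Simulated drying run sampled on the measurement cadence grid."""

    times_h: np.ndarray
    a_l: np.ndarray
    a_s: np.ndarray
    k1_t: np.ndarray
    k2_t: np.ndarray
    light: np.ndarray
    cum_leaf_loss: np.ndarray
    cum_soil_loss: np.ndarray
    wilt_time_h: Optional[float]
    water_wt_pct: Optional[np.ndarray] = None

    def to_series(self, plant_id: str = "sim",
                  genotype: str = "wildtype") -> WaterContentSeries:
        if self.water_wt_pct is None:
            raise ValueError("trajectory was simulated without an m_dry mapping")
        return WaterContentSeries(self.times_h, self.water_wt_pct, self.light,
                                  plant_id=plant_id, genotype=genotype)


def water_wt_pct_from_amount(a_l, m_dry: float):
    """Gravimetric water content: wt% = 100 a_l / (a_l + m_dry)."""
    a = np.asarray(a_l, dtype=float)
    return 100.0 * a / (a + m_dry)


def amount_from_water_wt_pct(wt_pct, m_dry: float):
    """Inverse wt% mapping: a_l = m_dry w / (1 - w), w = wt/100."""
    w = np.asarray(wt_pct, dtype=float) / 100.0
    if np.any(w >= 1.0):
        raise ValueError("wt% must be below 100")
    return m_dry * w / (1.0 - w)


def k2_profile(t_h, params: DryingParams, schedule: LightSchedule,
               wilted=False) -> np.ndarray:
    """Realized stomatal loss coefficient k2 at time(s) t_h.

    During light the exponential decay restarts at every dawn; in darkness
    k2 is the constant Gamma * k2_cs.  ``wilted`` may be a scalar or boolean
    array applying the post-wilt multiplier.
    """
    t = np.asarray(t_h, dtype=float)
    phase = np.mod(t - schedule.t0_h, schedule.period_h)
    light = phase < schedule.bright_h
    k2 = np.where(
        light,
        (params.k2_os - params.k2_cs) * np.exp(-phase / params.tau_h)
        + params.k2_cs,
        params.gamma_bright_dark * params.k2_cs,
    )
    k2 = np.where(np.asarray(wilted, dtype=bool),
                  k2 * params.k2_wilt_multiplier, k2)
    return k2 if k2.ndim else float(k2)


def k1_rate(a_l, a_s, k2_now, params: DryingParams, wilted=False):
    """Soil-to-leaf transfer coefficient.

    Zero once wilted (latching); otherwise the equilibrium demand
    k2 A_l / (A_s - A_l) clamped at k1_max, and k1_max outright when the
    content gradient is exhausted (A_s <= A_l).
    """
    a_l = np.asarray(a_l, dtype=float)
    a_s = np.asarray(a_s, dtype=float)
    k2_now = np.asarray(k2_now, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        demand = np.where(a_s > a_l, k2_now * a_l / (a_s - a_l), np.inf)
    k1 = np.minimum(demand, params.k1_max)
    k1 = np.where(np.asarray(wilted, dtype=bool), 0.0, k1)
    return k1 if k1.ndim else float(k1)


def _dense_solution(params: DryingParams, schedule: LightSchedule,
                    horizon_h: float, dt_h: float,
                    day_multipliers: Optional[np.ndarray]):
    bounds = np.concatenate(
        ([0.0], schedule.transitions(horizon_h), [horizon_h]))
    seg_len = np.diff(bounds)
    n_sub = np.maximum(1, np.ceil(seg_len / dt_h)).astype(np.int64)
    mult = (np.asarray(day_multipliers, dtype=float)
            if day_multipliers is not None else np.empty(0))
    return _kernel.integrate(
        bounds, n_sub, params.k1_max, params.k3, params.k2_os, params.k2_cs,
        params.tau_h, params.gamma_bright_dark, params.theta_wilt,
        params.a_l0, params.a_s0, schedule.period_h, schedule.bright_h,
        schedule.t0_h, params.k2_wilt_multiplier, mult)


def simulate_drying(params: DryingParams,
                    schedule: LightSchedule = LightSchedule(),
                    horizon_h: float = 12 * 24.0,
                    cadence_min: float = 25.0,
                    m_dry: Optional[float] = None,
                    dt_h: float = DEFAULT_DT_H,
                    day_multipliers: Optional[np.ndarray] = None) -> Trajectory:
    """Integrate the drying ODEs and sample on the measurement cadence.

    The integrator is restarted at every light transition and the wilting
    crossing is located and latched inside the step that contains it.  The
    returned trajectory carries the realized k1(t), k2(t) and the two
    cumulative loss integrals, so the water budget
    a_l + a_s + losses = a_l0 + a_s0 closes to solver accuracy.
    """
    if horizon_h <= 0:
        raise ValueError("horizon must be positive")
    t_d, al_d, as_d, _, _, cl_d, cs_d, wilt = _dense_solution(
        params, schedule, horizon_h, dt_h, day_multipliers)
    if not (np.all(np.isfinite(al_d)) and np.all(np.isfinite(as_d))):
        raise RuntimeError("drying ODE integration produced non-finite values")

    cadence_h = cadence_min / 60.0
    times = np.arange(0.0, horizon_h + 1e-9, cadence_h)
    a_l = np.interp(times, t_d, al_d)
    a_s = np.interp(times, t_d, as_d)
    cum_l = np.interp(times, t_d, cl_d)
    cum_s = np.interp(times, t_d, cs_d)
    wilt_time = float(wilt) if wilt >= 0 else None
    wilted = times >= wilt_time if wilt_time is not None else np.zeros_like(
        times, dtype=bool)
    k2_t = k2_profile(times, params, schedule, wilted=wilted)
    k1_t = k1_rate(a_l, a_s, k2_t, params, wilted=wilted)
    wt = water_wt_pct_from_amount(a_l, m_dry) if m_dry is not None else None
    return Trajectory(times_h=times, a_l=a_l, a_s=a_s, k1_t=k1_t, k2_t=k2_t,
                      light=schedule.is_light(times), cum_leaf_loss=cum_l,
                      cum_soil_loss=cum_s, wilt_time_h=wilt_time,
                      water_wt_pct=wt)


def simulate_wtpct(params: DryingParams, schedule: LightSchedule,
                   times_h: np.ndarray, m_dry: float,
                   dt_h: float = DEFAULT_DT_H) -> np.ndarray:
    """Model water content (wt%) at arbitrary observation times.

    Thin fast path used by the fitting engine; shares the integrator with
    :func:`simulate_drying`.
    """
    t_d, al_d, _, _, _, _, _, _ = _dense_solution(
        params, schedule, float(times_h[-1]) + 1e-9, dt_h, None)
    a_l = np.interp(times_h, t_d, al_d)
    return water_wt_pct_from_amount(a_l, m_dry)


def half_life_from_tau(tau_h: float) -> float:
    """Closure half-life t_1/2 = tau ln 2 of the light-period k2 decay."""
    if tau_h <= 0:
        raise ValueError("tau must be positive")
    return tau_h * math.log(2.0)


@dataclass(frozen=True)
class PhaseOptions:
    """Tunables for the three-phase segmentation of a drying curve."""

    recovery_tol_wtpct: float = 2.0     # shortfall that ends phase I
    collapse_threshold_wtpct: float = 50.0
    dark_gain_tol_wtpct: float = 0.5    # below this a night counts as no gain
    plateau_window_h: float = 24.0
    smooth_kernel: int = 5              # odd median-filter width (samples)
    tail_samples: int = 3


@dataclass(frozen=True)
class PhaseBoundaries:
    """End of phase I and start of phase III (hours); None if not reached."""

    phase_i_end_h: Optional[float]
    phase_iii_start_h: Optional[float]
    plateau_wtpct: float


def _dark_runs(light: np.ndarray) -> list[tuple[int, int]]:
    """Complete dark runs as (start, stop) index pairs, stop exclusive."""
    runs = []
    n = light.size
    i = 0
    while i < n:
        if not light[i]:
            j = i
            while j < n and not light[j]:
                j += 1
            if i > 0 and j < n:  # complete: bounded by light on both sides
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def segment_phases(series: WaterContentSeries,
                   options: PhaseOptions = PhaseOptions()) -> PhaseBoundaries:
    """Locate the phase I -> II and phase II -> III boundaries.

    Phase I ends at the first dark period after which the water content no
    longer recovers to within ``recovery_tol_wtpct`` of the initial plateau.
    Phase III starts at the first drop below the collapse threshold that is
    followed by no further dark-period water gain.  A series that never
    leaves phase I yields open (None) boundaries.
    """
    t = series.times_h
    if t[-1] - t[0] < 2 * 24.0:
        raise ValueError("phase segmentation needs at least two light cycles")
    k = options.smooth_kernel
    if k % 2 == 0:
        raise ValueError("smooth_kernel must be odd")
    w = medfilt(series.water_wt_pct, kernel_size=k) if k > 1 else \
        series.water_wt_pct.copy()

    plateau = float(np.mean(w[t <= t[0] + options.plateau_window_h]))
    runs = _dark_runs(series.light)
    m = options.tail_samples

    phase_i_end = None
    for (i, j) in runs:
        end_val = float(np.mean(w[max(i, j - m):j]))
        if end_val < plateau - options.recovery_tol_wtpct:
            phase_i_end = float(t[j - 1])
            break

    below = w < options.collapse_threshold_wtpct
    candidates = np.flatnonzero(below)
    phase_iii_start = None
    if candidates.size:
        # exclude candidates at or before the end of any gaining dark period
        t_guard = -np.inf
        for (i, j) in runs:
            start_val = float(np.mean(w[i:min(j, i + m)]))
            end_val = float(np.mean(w[max(i, j - m):j]))
            if end_val - start_val > options.dark_gain_tol_wtpct:
                t_guard = max(t_guard, float(t[j - 1]))
        ok = candidates[t[candidates] > t_guard]
        if ok.size:
            phase_iii_start = float(t[ok[0]])

    return PhaseBoundaries(phase_i_end_h=phase_i_end,
                           phase_iii_start_h=phase_iii_start,
                           plateau_wtpct=plateau)
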