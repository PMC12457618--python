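"""Per-plant parameter estimation and cohort statistics.

Each plant's water-content series is fitted by nonlinear least squares
against the forward drying simulation.  Free parameters default to the six
physiological quantities {k1_max, k2_os, k2_cs, tau, theta_wilt, a_s0}; the
bright-dark factor Gamma is a single empirically determined constant shared
by all plants, the initial leaf pool a_l0 is anchored to the observed
initial plateau, and the soil evaporation coefficient k3 is a configuration
constant (it is measured directly by plant-free gravimetric controls, and
the leaf water content alone is almost uninformative about it: freeing it
opens a flat k3/a_s0 ridge that degrades every other estimate; set
``vary_k3=True`` to free it anyway).  Rate-like parameters are optimised in
log10 space (they span orders of magnitude and must stay positive); k2_os
is parametrised through the positive increment dk2 = k2_os - k2_cs so the
open-stomata level can never fall below the closed-stomata level.

Fits are selected by goodness of fit (R^2 > 0.99 by default) before cohort
statistics are computed, mirroring the screening used for real campaigns in
which some plants die early or detach from the measurement window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    DEFAULT_DT_H,
    DryingParams,
    LightSchedule,
    PhaseOptions,
    amount_from_water_wt_pct,
    half_life_from_tau,
    segment_phases,
    simulate_wtpct,
)
from .series import WaterContentSeries

__all__ = [
    "FitOptions",
    "FitResult",
    "CohortComparison",
    "fit_drying_curve",
    "goodness_of_fit",
    "select_fits",
    "cohort_statistics",
]

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)

#: Parameters reported with uncertainties, in output order.
REPORTED = ("k1_max", "k3", "k2_os", "k2_cs", "tau_h", "theta_wilt", "a_s0")


@dataclass(frozen=True)
class FitOptions:
    """Controls for the per-plant fit."""

    gamma_bright_dark: float = 0.92   # global empirical constant, not fitted
    m_dry: float = 17.5               # amount units; fixes the wt% mapping
    k3: float = 1e-3                  # soil evaporation; fixed unless vary_k3
    vary_k3: bool = False
    initial_params: Optional[DryingParams] = None  # replace data-driven start
    n_starts: int = 8                 # multi-start count (first = data-driven)
    master_seed: int = 20250923       # seeds the start perturbations
    start_spread_dex: float = 0.2     # log10 SD of start perturbations
    dt_h: float = DEFAULT_DT_H
    weights: Optional[np.ndarray] = None  # uniform when None
    max_nfev: int = 2000
    diff_step: float = 1e-3   # finite-difference step in log10 space
    tol: float = 1e-10        # xtol/ftol/gtol for the trust-region solver


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters for one plant."""

    params: DryingParams
    stderr: dict
    r_squared: float
    t_half_h: float
    t_half_stderr_h: Optional[float]
    converged: bool
    objective: float
    residuals: np.ndarray
    predicted: np.ndarray
    plant_id: str
    genotype: str
    n_starts: int

    def value(self, name: str) -> float:
        if name == "t_half_h":
            return self.t_half_h
        return getattr(self.params, name)


def goodness_of_fit(series: WaterContentSeries,
                    predicted: np.ndarray) -> float:
    """Coefficient of determination R^2 = 1 - SS_res / SS_tot on wt% values."""
    obs = series.water_wt_pct
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != obs.shape:
        raise ValueError("prediction must align with the observed series")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("series has zero variance; R^2 undefined")
    ss_res = float(np.sum((obs - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def _initial_guess(series: WaterContentSeries, schedule: LightSchedule,
                   opts: FitOptions) -> tuple[float, dict]:
    """Data-driven starting point: plateau -> a_l0, phase III dark slope ->
    k2_cs, first phase II morning -> k2_os; order-of-magnitude defaults for
    the quantities the observable is blind to in phase I (k3, soil pool)."""
    t, w = series.times_h, series.water_wt_pct
    plateau = float(np.mean(w[t <= t[0] + 24.0]))
    plateau = min(plateau, 99.0)
    a_l0 = float(amount_from_water_wt_pct(plateau, opts.m_dry))

    guess = {
        "k1_max": 0.05,
        "k3": 1e-3,
        "k2_cs": 4e-3,
        "dk2": 0.05,
        "tau_h": 10.0,
        "theta_wilt": 0.4 * a_l0,
        "a_s0": 6.0 * a_l0,
    }
    try:
        pb = segment_phases(series, PhaseOptions())
    except ValueError:
        return a_l0, guess

    if pb.phase_i_end_h is None:
        raise ValueError(
            "series never leaves phase I; record a longer horizon before "
            "fitting the drying parameters")

    # amount-scale series for slope estimates (guard the wt% -> amount map)
    w_safe = np.clip(w, 0.5, 99.0)
    a_obs = np.asarray(amount_from_water_wt_pct(w_safe, opts.m_dry))

    # closed-stomata rate from the last complete dark period's log-slope
    dark = ~series.light
    runs = _runs(dark)
    late_runs = [r for r in runs if t[r[0]] > pb.phase_i_end_h]
    if late_runs:
        i, j = late_runs[-1]
        if j - i >= 4:
            slope = np.polyfit(t[i:j], np.log(a_obs[i:j]), 1)[0]
            if slope < -1e-5:
                guess["k2_cs"] = min(-slope / opts.gamma_bright_dark, 0.5)

    # open-stomata rate from the first morning drop after phase I
    morning = (t > pb.phase_i_end_h) & series.light \
        & (t <= pb.phase_i_end_h + 3.0)
    if np.sum(morning) >= 3:
        slope = np.polyfit(t[morning], np.log(a_obs[morning]), 1)[0]
        if slope < 0:
            guess["dk2"] = float(np.clip(-slope, 5e-3, 1.0))
    return a_l0, guess


def _ensure_informative_guess(guess: dict, a_l0: float, plateau: float,
                              series: WaterContentSeries,
                              schedule: LightSchedule,
                              opts: FitOptions) -> dict:
    """Raise the guessed stomatal amplitude until the guess curve actually
    enters phase II within the record.

    While the simulated curve stays in the phase-I equilibrium the model
    output is exactly the plateau constant, insensitive to every parameter,
    and a gradient-based fit cannot move.  The observed series did leave
    phase I (checked upstream), so a guess that never does is simply too
    weak; the morning-slope estimate underestimates k2_os because soil
    inflow partly masks the dawn water loss.
    """
    g = dict(guess)
    for _ in range(30):
        dp = DryingParams(
            k1_max=g["k1_max"], k3=g["k3"], k2_os=g["k2_cs"] + g["dk2"],
            k2_cs=g["k2_cs"], tau_h=g["tau_h"],
            gamma_bright_dark=opts.gamma_bright_dark,
            theta_wilt=min(g["theta_wilt"], 0.99 * g["a_s0"]),
            a_l0=a_l0, a_s0=g["a_s0"])
        wt = simulate_wtpct(dp, schedule, series.times_h, opts.m_dry,
                            dt_h=opts.dt_h)
        if wt.min() < plateau - 5.0:
            return g
        g["dk2"] *= 1.4
    return g


def _runs(flag: np.ndarray) -> list[tuple[int, int]]:
    out, n, i = [], flag.size, 0
    while i < n:
        if flag[i]:
            j = i
            while j < n and flag[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _make_params(guess: dict, a_l0: float) -> lmfit.Parameters:
    p = lmfit.Parameters()
    lg = math.log10
    p.add("lg_k1_max", value=lg(guess["k1_max"]), min=-4.0, max=1.0)
    p.add("lg_k3", value=lg(guess["k3"]), min=-6.0, max=-0.5)
    p.add("lg_k2_cs", value=lg(guess["k2_cs"]), min=-5.0, max=-0.5)
    p.add("lg_dk2", value=lg(guess["dk2"]), min=-4.0, max=0.5)
    p.add("lg_tau_h", value=lg(guess["tau_h"]), min=lg(0.5), max=lg(300.0))
    p.add("lg_theta", value=lg(max(guess["theta_wilt"], 1e-2)),
          min=-1.0, max=lg(a_l0 * 50))
    p.add("lg_a_s0", value=lg(guess["a_s0"]), min=lg(a_l0 * 1.05),
          max=lg(a_l0 * 100))
    return p


def _params_from_lmfit(p: lmfit.Parameters, a_l0: float,
                       opts: FitOptions) -> DryingParams:
    k2_cs = 10.0 ** p["lg_k2_cs"].value
    return DryingParams(
        k1_max=10.0 ** p["lg_k1_max"].value,
        k3=10.0 ** p["lg_k3"].value,
        k2_os=k2_cs + 10.0 ** p["lg_dk2"].value,
        k2_cs=k2_cs,
        tau_h=10.0 ** p["lg_tau_h"].value,
        gamma_bright_dark=opts.gamma_bright_dark,
        theta_wilt=min(10.0 ** p["lg_theta"].value,
                       0.999 * 10.0 ** p["lg_a_s0"].value),
        a_l0=a_l0,
        a_s0=10.0 ** p["lg_a_s0"].value,
    )


def fit_drying_curve(series: WaterContentSeries,
                     schedule: LightSchedule = LightSchedule(),
                     options: FitOptions = FitOptions()) -> FitResult:
    """Weighted least-squares fit of the drying model to one plant.

    Multi-start: the first start is the data-driven guess, the remaining
    ``n_starts - 1`` perturb it in log space with seeded Gaussian factors;
    the best final objective wins.  The master seed is a configuration
    constant, so refits are reproducible.
    """
    if options.initial_params is not None:
        ip = options.initial_params
        a_l0 = ip.a_l0
        guess = {"k1_max": ip.k1_max, "k3": ip.k3, "k2_cs": ip.k2_cs,
                 "dk2": ip.k2_os - ip.k2_cs, "tau_h": ip.tau_h,
                 "theta_wilt": ip.theta_wilt, "a_s0": ip.a_s0}
    else:
        a_l0, guess = _initial_guess(series, schedule, options)
        plateau = float(np.mean(
            series.water_wt_pct[series.times_h <= series.times_h[0] + 24.0]))
        guess = _ensure_informative_guess(guess, a_l0, plateau, series,
                                          schedule, options)
    obs = series.water_wt_pct
    w = options.weights if options.weights is not None else 1.0

    def residual(p: lmfit.Parameters) -> np.ndarray:
        try:
            dp = _params_from_lmfit(p, a_l0, options)
            model = simulate_wtpct(dp, schedule, series.times_h,
                                   options.m_dry, dt_h=options.dt_h)
        except (ValueError, RuntimeError):
            return np.full(obs.shape, 1e3)
        return (model - obs) * w

    rng = np.random.default_rng(options.master_seed)
    best = None
    for start in range(options.n_starts):
        g = dict(guess)
        if start > 0:
            factors = 10.0 ** (options.start_spread_dex
                               * rng.standard_normal(len(g)))
            g = {k: v * f for (k, v), f in zip(g.items(), factors)}
        try:
            pars = _make_params(g, a_l0)
            if not options.vary_k3:
                pars["lg_k3"].set(value=math.log10(options.k3), vary=False)
            # clip starting values into bounds after perturbation
            for par in pars.values():
                if par.vary:
                    par.value = float(np.clip(par.value, par.min, par.max))
            res = lmfit.minimize(residual, pars, method="least_squares",
                                 max_nfev=options.max_nfev,
                                 diff_step=options.diff_step,
                                 xtol=options.tol, ftol=options.tol,
                                 gtol=options.tol)
        except Exception as exc:  # pragma: no cover - solver pathologies
            logger.warning("fit start %d failed: %s", start, exc)
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")

    dp = _params_from_lmfit(best.params, a_l0, options)
    predicted = simulate_wtpct(dp, schedule, series.times_h, options.m_dry,
                               dt_h=options.dt_h)
    r2 = goodness_of_fit(series, predicted)
    stderr = _propagate_stderr(best, dp)
    tau_err = stderr.get("tau_h")
    return FitResult(
        params=dp,
        stderr=stderr,
        r_squared=r2,
        t_half_h=half_life_from_tau(dp.tau_h),
        t_half_stderr_h=(math.log(2.0) * tau_err
                         if tau_err is not None else None),
        converged=bool(best.success),
        objective=float(best.chisqr),
        residuals=np.asarray(predicted - obs),
        predicted=np.asarray(predicted),
        plant_id=series.plant_id,
        genotype=series.genotype,
        n_starts=options.n_starts,
    )


def _propagate_stderr(res: lmfit.minimizer.MinimizerResult,
                      dp: DryingParams) -> dict:
    """Delta-method errors from log10 space back to natural units."""
    out: dict[str, Optional[float]] = {k: None for k in REPORTED}
    if res.covar is None:
        return out
    names = list(res.var_names)
    cov = res.covar

    def var_of(name: str) -> Optional[float]:
        if name in names:
            return float(cov[names.index(name), names.index(name)])
        return None

    direct = {"k1_max": "lg_k1_max", "k3": "lg_k3", "tau_h": "lg_tau_h",
              "theta_wilt": "lg_theta", "a_s0": "lg_a_s0",
              "k2_cs": "lg_k2_cs"}
    for nat, lg in direct.items():
        v = var_of(lg)
        if v is not None:
            out[nat] = LN10 * getattr(dp, nat) * math.sqrt(v)
    # k2_os = k2_cs + dk2: combine the two log-space variances
    if "lg_k2_cs" in names and "lg_dk2" in names:
        i, j = names.index("lg_k2_cs"), names.index("lg_dk2")
        d_cs = LN10 * dp.k2_cs
        d_dk = LN10 * (dp.k2_os - dp.k2_cs)
        var = (d_cs**2 * cov[i, i] + d_dk**2 * cov[j, j]
               + 2.0 * d_cs * d_dk * cov[i, j])
        if var >= 0:
            out["k2_os"] = math.sqrt(var)
    return out


def select_fits(results: Sequence[FitResult],
                r2_threshold: float = 0.99) -> list[FitResult]:
    """Keep converged fits whose R^2 exceeds the threshold; log the rest."""
    kept = []
    for r in results:
        if not r.converged:
            logger.info("excluding %s: fit did not converge", r.plant_id)
        elif r.r_squared <= r2_threshold:
            logger.info("excluding %s: R^2 = %.4f <= %.2f", r.plant_id,
                        r.r_squared, r2_threshold)
        else:
            kept.append(r)
    return kept


@dataclass(frozen=True)
class CohortComparison:
    """Wildtype-vs-mutant summary over selected fits."""

    group_stats: pd.DataFrame         # mean/sd/sem per parameter and group
    ratio_k2os: float                 # mutant over wildtype, ratio of means
    ratio_k2os_stderr: float
    p_values: dict
    test: str
    n_wildtype: int
    n_mutant: int


def cohort_statistics(wildtype: Sequence[FitResult],
                      mutant: Sequence[FitResult],
                      test: str = "welch") -> CohortComparison:
    """Group means, the mutant/wildtype k2_os ratio and per-parameter tests.

    The headline ratio is the ratio of group means with first-order error
    propagation from the standard errors of the means,
    sigma_ratio = ratio * sqrt((sem_m / mu_m)^2 + (sem_w / mu_w)^2).
    Group differences use Welch's unequal-variance t-test by default
    (``test="mannwhitney"`` switches to the rank test).
    """
    if len(wildtype) < 2 or len(mutant) < 2:
        raise ValueError("need at least two selected fits per group")
    names = list(REPORTED) + ["t_half_h"]
    rows = []
    pvals = {}
    for name in names:
        vw = np.array([r.value(name) for r in wildtype])
        vm = np.array([r.value(name) for r in mutant])
        for label, v in (("wildtype", vw), ("mutant", vm)):
            rows.append({"parameter": name, "group": label,
                         "mean": v.mean(), "sd": v.std(ddof=1),
                         "sem": v.std(ddof=1) / math.sqrt(v.size),
                         "n": v.size})
        if vw.var(ddof=1) == 0 and vm.var(ddof=1) == 0:
            # degenerate case (e.g. a parameter held fixed in every fit)
            pvals[name] = 1.0 if vw.mean() == vm.mean() else 0.0
        elif test == "welch":
            pvals[name] = float(stats.ttest_ind(vm, vw, equal_var=False).pvalue)
        elif test == "mannwhitney":
            pvals[name] = float(stats.mannwhitneyu(
                vm, vw, alternative="two-sided").pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")

    table = pd.DataFrame(rows).set_index(["parameter", "group"])
    mu_w = table.loc[("k2_os", "wildtype"), "mean"]
    mu_m = table.loc[("k2_os", "mutant"), "mean"]
    sem_w = table.loc[("k2_os", "wildtype"), "sem"]
    sem_m = table.loc[("k2_os", "mutant"), "sem"]
    ratio = mu_m / mu_w
    ratio_err = ratio * math.sqrt((sem_m / mu_m) ** 2 + (sem_w / mu_w) ** 2)
    return CohortComparison(
        group_stats=table,
        ratio_k2os=float(ratio),
        ratio_k2os_stderr=float(ratio_err),
        p_values=pvals,
        test=test,
        n_wildtype=len(wildtype),
        n_mutant=len(mutant),
    )
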